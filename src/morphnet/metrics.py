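"""Graph-theory measures for binary brain networks.

Global measures: mean clustering coefficient (Cp), characteristic path
length (Lp, averaged over connected node pairs only), global efficiency
(Eg, mean inverse shortest-path length with 1/inf = 0), local efficiency
(Eloc), degree assortativity, and modularity.  Nodal measures: degree and
(unnormalized) betweenness.  Small-world normalization divides Cp and Lp by
their means over degree-preserving rewired null graphs: gamma = Cp/Cp_null,
lambda = Lp/Lp_null, sigma = gamma/lambda.

Disconnected graphs are handled with the usual connectome conventions: Lp
averages over the connected pairs and the number of disconnected pairs is
reported; Eg treats unreachable pairs as zero efficiency.  Undefined values
(Lp of an edgeless graph, assortativity of a regular graph) are returned as
NaN rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import BinaryNetwork

logger = logging.getLogger(__name__)


@dataclass
class GraphMetricsRecord:
    """All measures of one network at one sparsity level."""

    sparsity: float
    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    assortativity: float
    modularity: float
    nodal_degree: np.ndarray
    nodal_betweenness: np.ndarray
    gamma: float = np.nan
    lam: float = np.nan
    sigma: float = np.nan
    n_disconnected_pairs: int = 0
    subject_id: str = ""

    GLOBAL_NAMES = ("Cp", "Lp", "Eg", "Eloc", "assortativity", "modularity",
                    "gamma", "lam", "sigma")


@dataclass
class MetricCurve:
    """One metric's values over the sparsity grid plus its trapezoidal AUC."""

    metric: str
    sparsity: np.ndarray
    values: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.sparsity = np.asarray(self.sparsity, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.sparsity.shape != self.values.shape:
            raise ValueError("grid and values length mismatch")
        if self.sparsity.size < 2:
            self.auc = 0.0
        else:
            self.auc = float(np.trapezoid(self.values, self.sparsity))


def to_networkx(net: BinaryNetwork) -> nx.Graph:
    return nx.from_numpy_array(net.adjacency.astype(np.int8))


def _distances(adj: np.ndarray) -> np.ndarray:
    if adj.sum() == 0:
        d = np.full(adj.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(adj.astype(np.int8)), method="D",
                         unweighted=True, directed=False)


def characteristic_path_length(adj: np.ndarray) -> tuple[float, int]:
    """Mean shortest-path length over connected ordered pairs; also the count
    of disconnected ordered pairs."""
    d = _distances(adj)
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_disc = int(off.sum() - finite.sum())
    if finite.sum() == 0:
        return float("nan"), n_disc
    return float(d[finite].mean()), n_disc


def global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d over all ordered node pairs, with 1/inf = 0."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def clustering_mean(adj: np.ndarray) -> float:
    """Mean triangle-based clustering; nodes with degree < 2 contribute 0."""
    a = adj.astype(np.float64)
    k = a.sum(axis=1)
    tri = np.diagonal(a @ a @ a)  # 2 * triangles per node ... actually 2T_i
    denom = k * (k - 1)
    c = np.zeros_like(k)
    ok = denom > 0
    c[ok] = tri[ok] / denom[ok]
    return float(c.mean())


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighborhood subgraph."""
    n = adj.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size >= 2:
            vals[i] = global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return float(vals.mean())


def degree_assortativity(adj: np.ndarray) -> float:
    """Pearson correlation of degrees across edge endpoints (both orientations)."""
    deg = adj.sum(axis=1).astype(np.float64)
    i, j = np.nonzero(np.triu(adj, k=1))
    if i.size == 0:
        return float("nan")
    x = np.concatenate([deg[i], deg[j]])
    y = np.concatenate([deg[j], deg[i]])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def best_modularity(net: BinaryNetwork, n_restarts: int = 10,
                    seed: int = 0) -> float:
    """Best Louvain partition quality over seeded restarts."""
    g = to_networkx(net)
    if g.number_of_edges() == 0:
        return float("nan")
    best = -np.inf
    for k in range(n_restarts):
        parts = nx.community.louvain_communities(g, seed=seed + k)
        q = nx.community.modularity(g, parts)
        best = max(best, q)
    return float(best)


def nodal_metrics(net: BinaryNetwork,
                  normalized: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Degree and shortest-path betweenness per node.

    Betweenness is reported as raw pair counts (each unordered source-target
    pair counted once, endpoints excluded); ``normalized=True`` divides by
    (R-1)(R-2)/2.
    """
    deg = net.adjacency.sum(axis=1).astype(np.float64)
    g = to_networkx(net)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    btw = np.array([bc[i] for i in range(net.n_nodes)], dtype=np.float64)
    return deg, btw


def global_metrics(net: BinaryNetwork, modularity_restarts: int = 10,
                   modularity_seed: int = 0) -> dict[str, float]:
    """All global measures of one binary network.

    Returns a dict with keys Cp, Lp, Eg, Eloc, assortativity, modularity and
    n_disconnected_pairs; undefined values are NaN.
    """
    adj = net.adjacency
    if net.n_edges == 0:
        logger.warning("edgeless graph: Lp undefined, reported as NaN")
        return {"Cp": 0.0, "Lp": float("nan"), "Eg": 0.0, "Eloc": 0.0,
                "assortativity": float("nan"), "modularity": float("nan"),
                "n_disconnected_pairs": net.n_nodes * (net.n_nodes - 1)}
    lp, n_disc = characteristic_path_length(adj)
    if n_disc:
        logger.info("Lp averaged over connected pairs; %d ordered pairs "
                    "disconnected", n_disc)
    return {
        "Cp": clustering_mean(adj),
        "Lp": lp,
        "Eg": global_efficiency(adj),
        "Eloc": local_efficiency(adj),
        "assortativity": degree_assortativity(adj),
        "modularity": best_modularity(net, modularity_restarts, modularity_seed),
        "n_disconnected_pairs": n_disc,
    }


def _swap_kernel_py(adj, edges, nswap, max_tries, seed):  # pragma: no cover
    np.random.seed(seed)
    m = edges.shape[0]
    swaps = tries = 0
    while swaps < nswap and tries < max_tries:
        tries += 1
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # propose (a-b),(c-d) -> (a-d),(c-b)
        if a == d or c == b or adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        swaps += 1
    return swaps


_swap_kernel = None


def _get_swap_kernel():
    global _swap_kernel
    if _swap_kernel is None:
        from numba import njit
        _swap_kernel = njit(cache=False)(_swap_kernel_py)
    return _swap_kernel


def rewire_preserving_degree(net: BinaryNetwork, n_swaps_per_edge: int = 10,
                             seed: int = 0) -> BinaryNetwork:
    """Degree-preserving randomization by repeated double edge swaps.

    Two edges (a-b), (c-d) are replaced by (a-d), (c-b) when that creates no
    self-loop or duplicate edge; the degree sequence is invariant.
    Deterministic given ``seed``.  If the graph admits no legal swap within
    the try budget it is returned unchanged with a warning.
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    adj = net.adjacency.copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    nswap = n_swaps_per_edge * net.n_edges
    kernel = _get_swap_kernel()
    swaps = kernel(adj, edges, nswap, max(100, 20 * nswap),
                   int(seed) % (2**32 - 1))
    if swaps < nswap:
        logger.warning("degree-preserving rewiring incomplete: "
                       "%d of %d swaps achieved", swaps, nswap)
    return BinaryNetwork(adjacency=adj, sparsity=net.sparsity,
                         region_ids=net.region_ids, subject_id=net.subject_id)


def small_worldness(net: BinaryNetwork, n_null: int = 100,
                    n_swaps_per_edge: int = 10,
                    seed: int = 0) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against degree-preserving rewired nulls.

    gamma = Cp / mean(Cp_null), lambda = Lp / mean(Lp_null),
    sigma = gamma / lambda.  A small-world graph shows gamma >> 1,
    lambda ~ 1, sigma > 1.
    """
    cp = clustering_mean(net.adjacency)
    lp, _ = characteristic_path_length(net.adjacency)
    if not np.isfinite(lp):
        raise ValueError("Lp undefined for this graph; small-worldness needs "
                         "a connected-enough network")
    cps, lps = [], []
    for k in range(n_null):
        null = rewire_preserving_degree(net, n_swaps_per_edge, seed=seed + k)
        cps.append(clustering_mean(null.adjacency))
        lp_null, _ = characteristic_path_length(null.adjacency)
        lps.append(lp_null)
    cp_null = float(np.mean(cps))
    lp_null = float(np.nanmean(lps))
    if cp_null == 0 or not np.isfinite(lp_null) or lp_null == 0:
        logger.warning("degenerate null ensemble (mean Cp=%.3g, mean Lp=%.3g)",
                       cp_null, lp_null)
        return float("nan"), float("nan"), float("nan")
    gamma = cp / cp_null
    lam = lp / lp_null
    return float(gamma), float(lam), float(gamma / lam)


def metrics_record(net: BinaryNetwork, n_null: int = 0,
                   n_swaps_per_edge: int = 10, seed: int = 0,
                   modularity_restarts: int = 10) -> GraphMetricsRecord:
    """Convenience: every measure of one network, optionally with small-world
    normalization (``n_null`` > 0)."""
    gm = global_metrics(net, modularity_restarts, modularity_seed=seed)
    deg, btw = nodal_metrics(net)
    gamma = lam = sigma = float("nan")
    if n_null > 0 and net.n_edges >= 2 and np.isfinite(gm["Lp"]):
        gamma, lam, sigma = small_worldness(net, n_null, n_swaps_per_edge, seed)
    return GraphMetricsRecord(
        sparsity=net.sparsity, Cp=gm["Cp"], Lp=gm["Lp"], Eg=gm["Eg"],
        Eloc=gm["Eloc"], assortativity=gm["assortativity"],
        modularity=gm["modularity"], nodal_degree=deg, nodal_betweenness=btw,
        gamma=gamma, lam=lam, sigma=sigma,
        n_disconnected_pairs=gm["n_disconnected_pairs"],
        subject_id=net.subject_id)


def metric_curves(records: list[GraphMetricsRecord]) -> list[MetricCurve]:
    """Per-metric curves and trapezoidal AUC over a shared sparsity grid."""
    if not records:
        raise ValueError("no records")
    grid = np.array([r.sparsity for r in records], dtype=np.float64)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("records must be ordered by strictly increasing sparsity")
    curves = []
    for name in GraphMetricsRecord.GLOBAL_NAMES:
        vals = np.array([getattr(r, name) for r in records])
        curves.append(MetricCurve(metric=name, sparsity=grid, values=vals))
    for name in ("nodal_degree", "nodal_betweenness"):
        vals = np.array([getattr(r, name).mean() for r in records])
        curves.append(MetricCurve(metric=f"mean_{name}", sparsity=grid, values=vals))
    return curves
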