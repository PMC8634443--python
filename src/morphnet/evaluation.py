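"""End-to-end evaluation runs: recovery rates, calibration and oracle checks.

Each function here re-runs a piece of the pipeline on freshly generated
synthetic cohorts (or on the published demographic summary, which is an
input) and measures how well the planted truth is recovered.  The functions
are shared by the test suite and the standalone acceptance script; all
randomness is controlled by explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import images, metrics, network, stats, vbm
from .simulate import (CohortSpec, generate_atlas, generate_gm_cohort,
                       generate_network_cohort)

#: Printed demographic/clinical summary used as input (per group: mean, sd, n).
TABLE1_SUMMARY = {
    "age": {"HC": (32.36, 4.93, 22), "NSZ": (31.22, 6.54, 23),
            "VSZ": (33.61, 8.62, 18)},
    "education": {"HC": (12.48, 2.61, 22), "NSZ": (12.78, 2.98, 23),
                  "VSZ": (11.56, 2.97, 18)},
    "duration": {"NSZ": (16.1, 28.88, 23), "VSZ": (59.89, 65.25, 18)},
    "PANSS": {"NSZ": (86.3, 16.49, 23), "VSZ": (112.0, 7.4, 18)},
    "MOAS": {"NSZ": (14.96, 3.99, 23), "VSZ": (29.0, 3.33, 18)},
}


def table1_statistics() -> dict[str, float]:
    """The five demographic test statistics recomputed from the summary table."""
    out = {}
    for var in ("age", "education"):
        g = TABLE1_SUMMARY[var]
        res = stats.anova_from_summary(
            [g[k][0] for k in ("HC", "NSZ", "VSZ")],
            [g[k][1] for k in ("HC", "NSZ", "VSZ")],
            [g[k][2] for k in ("HC", "NSZ", "VSZ")])
        out[f"F_{var}"] = res.statistic
    for var in ("duration", "PANSS", "MOAS"):
        g = TABLE1_SUMMARY[var]
        res = stats.pooled_t_from_summary(*g["VSZ"], *g["NSZ"],
                                          labels=("VSZ", "NSZ"))
        out[f"t_{var}"] = res.statistic
    return out


def similarity_matrix_dimension(seed: int = 0) -> int:
    """Build one synthetic subject's network on the AAL-90 parcellation and
    return its dimension."""
    spec = CohortSpec(n_per_group=(1, 1, 1), seed=seed)
    atlas = generate_atlas(spec.grid_shape, spec.n_regions, spec.seed,
                           spec.voxel_size_mm)
    maps, _, _ = generate_gm_cohort(spec, atlas)
    rs = images.extract_regional_samples(maps[0], atlas)
    sim = network.build_similarity_matrix(rs, list(atlas.region_ids))
    return sim.values.shape[0]


# ---------------------------------------------------------------------------
# graph-metric brute-force oracles (independent of the metrics module)

def floyd_warshall_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def brute_lp_eg(adj: np.ndarray) -> tuple[float, float]:
    d = floyd_warshall_distances(adj)
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = d[finite].mean() if finite.any() else float("nan")
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    eg = inv[off].sum() / (n * (n - 1))
    return float(lp), float(eg)


def brute_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[a, b] for ai, a in enumerate(nbrs)
                    for b in nbrs[ai + 1:])
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration of all shortest paths (small n)."""
    import itertools
    n = adj.shape[0]
    d = floyd_warshall_distances(adj)
    btw = np.zeros(n)
    nodes = range(n)
    for s, t in itertools.combinations(nodes, 2):
        if not np.isfinite(d[s, t]):
            continue
        # enumerate shortest paths by DFS along distance-decreasing edges
        paths: list[list[int]] = []
        stack = [[s]]
        while stack:
            path = stack.pop()
            u = path[-1]
            if u == t:
                paths.append(path)
                continue
            for v in np.flatnonzero(adj[u]):
                if d[v, t] == d[u, t] - 1:
                    stack.append(path + [int(v)])
        inner = np.zeros(n)
        for p in paths:
            for v in p[1:-1]:
                inner[v] += 1
        btw += inner / len(paths)
    return btw


def graph_metric_oracle_errors(n_graphs: int = 50, seed: int = 0) -> dict[str, float]:
    """Max |implementation - brute force| over random graphs of <= 10 nodes."""
    rng = np.random.default_rng(seed)
    errs = {"degree": 0.0, "betweenness": 0.0, "Cp": 0.0, "Lp": 0.0, "Eg": 0.0}
    for _ in range(n_graphs):
        n = int(rng.integers(4, 11))
        p = float(rng.uniform(0.25, 0.8))
        adj = rng.random((n, n)) < p
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        net = network.BinaryNetwork(adjacency=adj, sparsity=0.5)
        deg, btw = metrics.nodal_metrics(net)
        lp, _ = metrics.characteristic_path_length(adj)
        eg = metrics.global_efficiency(adj)
        cp = metrics.clustering_mean(adj)
        lp_o, eg_o = brute_lp_eg(adj)
        errs["degree"] = max(errs["degree"],
                             float(np.abs(deg - adj.sum(1)).max()))
        errs["betweenness"] = max(errs["betweenness"],
                                  float(np.abs(btw - brute_betweenness(adj)).max()))
        errs["Cp"] = max(errs["Cp"], abs(cp - brute_clustering(adj)))
        if np.isfinite(lp) or np.isfinite(lp_o):
            errs["Lp"] = max(errs["Lp"], abs(lp - lp_o))
        errs["Eg"] = max(errs["Eg"], abs(eg - eg_o))
    return errs


def gaussian_kl_oracle(mu1: float = 0.4, mu2: float = 0.6, sigma: float = 0.05,
                       n_grid: int = 4096) -> dict[str, float]:
    """Discrete symmetric KL between densely sampled Gaussians vs closed form
    (mu1-mu2)^2 / sigma^2 for equal variances."""
    lo = min(mu1, mu2) - 7 * sigma
    hi = max(mu1, mu2) + 7 * sigma
    grid = np.linspace(lo, hi, n_grid)

    def gauss(mu):
        d = np.exp(-0.5 * ((grid - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        return network.DensityEstimate(grid=grid, density=d, bandwidth=sigma)

    p, q = gauss(mu1), gauss(mu2)
    discrete = network.symmetric_kl(p, q)
    closed = (mu1 - mu2) ** 2 / sigma**2
    return {"discrete": float(discrete), "closed_form": float(closed),
            "rel_error": float(abs(discrete - closed) / closed),
            "self_similarity": network.kl_similarity(p, p)}


# ---------------------------------------------------------------------------
# stochastic recovery runs

def small_world_run(n_seeds: int = 10, n_null: int = 20,
                    n_swaps_per_edge: int = 10, base_seed: int = 0,
                    n: int = 90, k: int = 8, p_ws: float = 0.1) -> dict:
    """Small-world indices of Watts-Strogatz vs Erdos-Renyi graphs."""
    import networkx as nx
    ws_ok = er_ok = 0
    ws_sigmas, er_sigmas = [], []
    for s in range(n_seeds):
        g = nx.watts_strogatz_graph(n, k, p_ws, seed=base_seed + s)
        net = network.BinaryNetwork(nx.to_numpy_array(g).astype(bool),
                                    sparsity=k / (n - 1))
        gam, lam, sig = metrics.small_worldness(net, n_null, n_swaps_per_edge,
                                                seed=base_seed + 1000 + s)
        ws_sigmas.append(sig)
        ws_ok += int(gam > 1 and sig > 1)
        g = nx.gnm_random_graph(n, n * k // 2, seed=base_seed + s)
        net = network.BinaryNetwork(nx.to_numpy_array(g).astype(bool),
                                    sparsity=k / (n - 1))
        _, _, sig_er = metrics.small_worldness(net, n_null, n_swaps_per_edge,
                                               seed=base_seed + 2000 + s)
        er_sigmas.append(sig_er)
        er_ok += int(0.8 <= sig_er <= 1.2)
    return {"ws_pass": ws_ok, "er_pass": er_ok, "n_seeds": n_seeds,
            "ws_sigma_mean": float(np.mean(ws_sigmas)),
            "er_sigma_mean": float(np.mean(er_sigmas))}


def vbm_recovery(seed: int, fwhm_mm: float = 8.0, q: float = 0.05,
                 min_cluster: int = 30) -> dict:
    """One seed of the full voxelwise pipeline on the default image cohort."""
    spec = CohortSpec(seed=seed)
    atlas = generate_atlas(spec.grid_shape, spec.n_regions, spec.seed,
                           spec.voxel_size_mm)
    maps, design, truth = generate_gm_cohort(spec, atlas)
    smoothed = [images.smooth_gm_map(m, fwhm_mm) for m in maps]
    statmap = vbm.voxelwise_anova(smoothed, design, ["PANSS", "duration"])
    surv = vbm.fdr_threshold(statmap, q)
    clusters = vbm.cluster_filter(surv, min_cluster, statmap)
    planted = atlas.labels == truth.planted_region_id
    hit = [c for c in clusters if planted[tuple(c.voxels.T)].any()]
    detected = len(hit) > 0
    ordered = False
    significant = False
    if detected:
        means = vbm.cluster_mean_gmv(smoothed, hit[0])
        g = design.groups
        m_hc, m_nsz, m_vsz = (means[g == x].mean() for x in ("HC", "NSZ", "VSZ"))
        ordered = m_hc > m_nsz > m_vsz
        tests = vbm.posthoc_cluster_tests(means, design)
        significant = all(r.p_adj < 0.05 for r in tests)
    raw_means = np.array([m.values[planted].mean() for m in maps])
    g = design.groups
    raw_ordered = (raw_means[g == "HC"].mean() > raw_means[g == "NSZ"].mean()
                   > raw_means[g == "VSZ"].mean())
    return {"detected": detected, "ordered": ordered, "significant": significant,
            "raw_region_ordered": bool(raw_ordered),
            "n_clusters": len(clusters)}


def vbm_recovery_rates(n_seeds: int = 20, base_seed: int = 0) -> dict:
    runs = [vbm_recovery(base_seed + s) for s in range(n_seeds)]
    return {
        "detect_rate": float(np.mean([r["detected"] for r in runs])),
        "order_rate": float(np.mean([r["detected"] and r["ordered"]
                                     for r in runs])),
        "raw_region_order_rate": float(np.mean([r["raw_region_ordered"]
                                                for r in runs])),
        "n_seeds": n_seeds,
    }


def topology_gradient(seed: int) -> dict:
    """One seed of the network-cohort group comparison."""
    nets, design, truth = generate_network_cohort(CohortSpec(seed=seed))
    eg = np.array([metrics.global_efficiency(n.adjacency) for n in nets])
    lp = np.array([metrics.characteristic_path_length(n.adjacency)[0]
                   for n in nets])
    g = design.groups
    eg_means = [eg[g == x].mean() for x in ("HC", "NSZ", "VSZ")]
    lp_means = [lp[g == x].mean() for x in ("HC", "NSZ", "VSZ")]
    eg_tests = stats.posthoc_bonferroni(eg, design)
    lp_tests = stats.posthoc_bonferroni(lp, design)
    return {
        "eg_increasing": eg_means[0] < eg_means[1] < eg_means[2],
        "lp_decreasing": lp_means[0] > lp_means[1] > lp_means[2],
        "all_pairs_significant": all(r.p_adj < 0.05
                                     for r in eg_tests + lp_tests),
    }


def topology_gradient_rate(n_seeds: int = 20, base_seed: int = 0) -> dict:
    runs = [topology_gradient(base_seed + s) for s in range(n_seeds)]
    ok = [r["eg_increasing"] and r["lp_decreasing"]
          and r["all_pairs_significant"] for r in runs]
    return {"pass_rate": float(np.mean(ok)), "n_seeds": n_seeds}


def correlation_sign_recovery(seed: int, q: float = 0.05) -> dict:
    """One seed: are the planted clinical-coupling signs recovered with FDR?

    Measures: planted-region mean GM, Eg, Lp and the planted node's degree;
    scores: PANSS and MOAS over patients.  Required pattern: GM and nodal
    degree negative against both scores, Eg positive and Lp negative against
    MOAS.
    """
    spec = CohortSpec(seed=seed)
    atlas = generate_atlas(spec.grid_shape, spec.n_regions, spec.seed,
                           spec.voxel_size_mm)
    maps, design_img, truth_img = generate_gm_cohort(spec, atlas)
    nets, design_net, truth_net = generate_network_cohort(spec)
    planted = atlas.labels == truth_img.planted_region_id
    gmv = np.array([m.values[planted].mean() for m in maps])
    eg = np.array([metrics.global_efficiency(n.adjacency) for n in nets])
    lp = np.array([metrics.characteristic_path_length(n.adjacency)[0]
                   for n in nets])
    deg0 = truth_net.planted_node_degree.astype(float)
    measures = pd.DataFrame({"subject_id": design_img.table["subject_id"],
                             "gmv": gmv, "Eg": eg, "Lp": lp, "degree": deg0})
    patients = design_img.patients().table
    scores = patients[["subject_id", "PANSS", "MOAS"]]
    measures = measures[measures["subject_id"].isin(patients["subject_id"])]
    results = stats.clinical_correlations(measures, scores, q=q)
    res = {r.comparison: r for r in results}

    def ok(name: str, sign: int) -> bool:
        r = res[name]
        return np.sign(r.statistic) == sign and r.p_adj < q

    required = {
        "gmv vs PANSS": -1, "gmv vs MOAS": -1,
        "degree vs PANSS": -1, "degree vs MOAS": -1,
        "Eg vs MOAS": +1, "Lp vs MOAS": -1,
    }
    flags = {k: ok(k, v) for k, v in required.items()}
    return {"all_signs_recovered": all(flags.values()), "flags": flags}


def correlation_sign_rate(n_seeds: int = 20, base_seed: int = 0) -> dict:
    runs = [correlation_sign_recovery(base_seed + s) for s in range(n_seeds)]
    return {"pass_rate": float(np.mean([r["all_signs_recovered"] for r in runs])),
            "n_seeds": n_seeds}


def ancova_type1_rate(n_reps: int = 1000, alpha: float = 0.05,
                      seed: int = 0, n_per_group=(22, 23, 18),
                      n_covariates: int = 2) -> float:
    """Rejection rate of the group partial F under the global null."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["HC", "NSZ", "VSZ"], n_per_group)
    n = groups.size
    hits = 0
    for _ in range(n_reps):
        y = rng.standard_normal(n)
        cov = rng.standard_normal((n, n_covariates))
        _, p, _ = stats.partial_f_group(y, groups, cov)
        hits += p < alpha
    return hits / n_reps


def fdr_family_fdp(n_families: int = 1000, n_tests: int = 8, n_true: int = 4,
                   n_obs: int = 40, q: float = 0.05, effect: float = 0.8,
                   seed: int = 0) -> float:
    """Mean false-discovery proportion of BH over simulated correlation
    families with ``n_true`` strong planted effects per family."""
    from scipy import stats as sps
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_families):
        pvals, is_null = [], []
        for t in range(n_tests):
            x = rng.standard_normal(n_obs)
            if t < n_true:
                y = effect * x + rng.standard_normal(n_obs)
                is_null.append(False)
            else:
                y = rng.standard_normal(n_obs)
                is_null.append(True)
            pvals.append(sps.pearsonr(x, y).pvalue)
        reject, _ = stats.fdr_bh(np.array(pvals), q)
        n_rej = int(reject.sum())
        n_false = int((reject & np.array(is_null)).sum())
        fdps.append(n_false / n_rej if n_rej else 0.0)
    return float(np.mean(fdps))
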