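"""Individual morphological covariance network construction.

For one subject, each atlas region contributes the empirical distribution of
its voxel GM values.  A Gaussian-kernel density estimate of every region's
distribution is compared to every other region's on a shared grid with the
symmetrized Kullback-Leibler divergence D = KL(p||q) + KL(q||p); the edge
weight is exp(-D), a similarity in (0, 1].  Thresholding the resulting R x R
similarity matrix at a target sparsity (fraction of possible edges kept)
yields one binary graph per subject per sparsity level.

The functional form exp(-(KL(p||q)+KL(q||p))) follows the individual
morphological network literature: it is symmetric, maps divergence 0 to
similarity 1, and decays toward 0 as distributions separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import RegionalSamples

DENSITY_FLOOR = 1e-10


@dataclass
class DensityEstimate:
    """A probability density evaluated on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise ValueError("grid and density must be matching 1D vectors")
        d = np.diff(self.grid)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-8):
            raise ValueError("grid must be strictly increasing and uniform")

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def variance(self) -> float:
        m = self.mean()
        return float(np.trapezoid((self.grid - m) ** 2 * self.density, self.grid))


@dataclass
class SimilarityMatrix:
    """Per-subject R x R morphological similarity matrix (unit diagonal)."""

    subject_id: str
    values: np.ndarray
    region_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        r = len(self.region_ids)
        if self.values.shape != (r, r):
            raise ValueError("matrix shape does not match region count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")


@dataclass
class BinaryNetwork:
    """Undirected simple graph as a boolean adjacency matrix at one sparsity."""

    adjacency: np.ndarray
    sparsity: float
    region_ids: list[int] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diagonal(a)):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def silverman_bandwidth(samples: np.ndarray, factor: float = 1.0) -> float:
    """Silverman's rule-of-thumb bandwidth, robust (min of sd and IQR/1.34)."""
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError(
            "degenerate bandwidth: all sample values identical "
            "(enable the jitter option to proceed)")
    return factor * 0.9 * spread * n ** (-0.2)


def _kde_on_grid(samples: np.ndarray, grid: np.ndarray, bandwidth: float,
                 floor: float = DENSITY_FLOOR) -> np.ndarray:
    """Gaussian KDE evaluated on a grid, floored and renormalized to integrate to 1."""
    x = np.asarray(samples, dtype=np.float64)
    z = (grid[None, :] - x[:, None]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=0)
    dens /= x.size * bandwidth * np.sqrt(2.0 * np.pi)
    dens = np.maximum(dens, floor)
    dens /= np.trapezoid(dens, grid)
    return dens


def estimate_density(samples: np.ndarray, n_grid: int = 128,
                     bandwidth_rule: str = "silverman",
                     bandwidth_factor: float = 1.0,
                     bandwidth: float | None = None,
                     support: tuple[float, float] | None = None,
                     pad_bandwidths: float = 3.0) -> DensityEstimate:
    """Gaussian-kernel KDE of a sample vector on a uniform grid.

    The grid spans ``support`` if given, otherwise [min, max] of the samples
    padded by ``pad_bandwidths`` bandwidths to capture the kernel tails.
    Densities are floored at 1e-10 and renormalized so the trapezoidal
    integral is 1.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1D vector of at least 2 samples")
    if np.unique(x).size < 2:
        raise ValueError(
            "all sample values identical; KDE bandwidth is degenerate "
            "(enable the jitter option to proceed)")
    if n_grid < 32:
        raise ValueError("n_grid must be >= 32")
    if bandwidth is None:
        if bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule: {bandwidth_rule!r}")
        bandwidth = silverman_bandwidth(x, bandwidth_factor)
    if support is None:
        lo = x.min() - pad_bandwidths * bandwidth
        hi = x.max() + pad_bandwidths * bandwidth
    else:
        lo, hi = support
    grid = np.linspace(lo, hi, n_grid)
    dens = _kde_on_grid(x, grid, bandwidth)
    return DensityEstimate(grid=grid, density=dens, bandwidth=float(bandwidth))


def symmetric_kl(p: DensityEstimate, q: DensityEstimate) -> float:
    """Discrete symmetrized KL divergence, summed as density x grid spacing."""
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("densities must share an identical grid")
    if not (np.all(np.isfinite(p.density)) and np.all(np.isfinite(q.density))):
        raise ValueError("non-finite density values")
    dx = p.spacing
    pd_ = np.maximum(p.density, DENSITY_FLOOR)
    qd = np.maximum(q.density, DENSITY_FLOOR)
    d = float(np.sum((pd_ - qd) * (np.log(pd_) - np.log(qd))) * dx)
    return d


def kl_similarity(p: DensityEstimate, q: DensityEstimate) -> float:
    """Similarity exp(-(KL(p||q)+KL(q||p))) in (0, 1]; 1 iff p == q on the grid."""
    d = symmetric_kl(p, q)
    return float(np.exp(-max(d, 0.0)))


def build_similarity_matrix(samples: RegionalSamples,
                            region_ids: list[int] | None = None,
                            n_grid: int = 128,
                            bandwidth_factor: float = 1.0,
                            pad_bandwidths: float = 3.0,
                            jitter: bool = False,
                            jitter_amplitude: float = 1e-6,
                            rng: np.random.Generator | None = None) -> SimilarityMatrix:
    """All-pairs KL similarity over one subject's regional distributions.

    Each pair is evaluated on its own shared uniform grid spanning the union
    of the two regions' sample ranges, padded by ``pad_bandwidths`` times the
    larger of the two bandwidths.  Deterministic given the samples and
    configuration (jitter, off by default, draws from ``rng``).
    """
    ids = [int(r) for r in (region_ids or samples.region_ids())]
    vecs: dict[int, np.ndarray] = {}
    for rid in ids:
        if rid not in samples.samples:
            raise ValueError(f"region {rid} missing from samples")
        v = np.asarray(samples.samples[rid], dtype=np.float64)
        if np.unique(v).size < 2:
            if not jitter:
                raise ValueError(
                    f"region {rid}: all sample values identical; enable jitter")
            gen = rng if rng is not None else np.random.default_rng(0)
            v = v + gen.uniform(-jitter_amplitude, jitter_amplitude, size=v.size)
        vecs[rid] = v
    bw = {rid: silverman_bandwidth(vecs[rid], bandwidth_factor) for rid in ids}
    r = len(ids)
    mat = np.eye(r)
    for i in range(r):
        xi = vecs[ids[i]]
        for j in range(i + 1, r):
            xj = vecs[ids[j]]
            try:
                h = max(bw[ids[i]], bw[ids[j]])
                lo = min(xi.min(), xj.min()) - pad_bandwidths * h
                hi = max(xi.max(), xj.max()) + pad_bandwidths * h
                grid = np.linspace(lo, hi, n_grid)
                pi = _kde_on_grid(xi, grid, bw[ids[i]])
                pj = _kde_on_grid(xj, grid, bw[ids[j]])
                dx = grid[1] - grid[0]
                d = float(np.sum((pi - pj) * (np.log(pi) - np.log(pj))) * dx)
            except (ValueError, FloatingPointError) as exc:
                raise ValueError(
                    f"density estimation failed for region pair "
                    f"({ids[i]}, {ids[j]}): {exc}") from exc
            mat[i, j] = mat[j, i] = np.exp(-max(d, 0.0))
    return SimilarityMatrix(subject_id=samples.subject_id, values=mat, region_ids=ids)


def binarize_at_sparsity(matrix: SimilarityMatrix, sparsity: float) -> BinaryNetwork:
    """Keep the top-K off-diagonal similarities, K = floor(sparsity * R(R-1)/2).

    Ties at the threshold are broken by ascending (row, column) lexicographic
    order of the upper-triangle pairs, so the edge set is deterministic.
    """
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must be in (0, 1)")
    w = matrix.values
    r = w.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    k = int(np.floor(sparsity * r * (r - 1) / 2))
    adj = np.zeros((r, r), dtype=bool)
    if k > 0:
        # sort by (-weight, i, j): lexicographic tie-break is the natural order
        # of triu_indices, and np.argsort(kind="stable") preserves it
        order = np.argsort(-w[iu, ju], kind="stable")[:k]
        adj[iu[order], ju[order]] = True
        adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=float(sparsity),
                         region_ids=matrix.region_ids, subject_id=matrix.subject_id)


def sparsity_grid(s_min: float = 0.05, s_max: float = 0.39,
                  s_step: float = 0.02) -> np.ndarray:
    """The sparsity levels analysed, default 0.05 to 0.39 in steps of 0.02."""
    if not (0.0 < s_min <= s_max < 1.0) or s_step <= 0:
        raise ValueError("require 0 < s_min <= s_max < 1 and s_step > 0")
    n = int(np.floor((s_max - s_min) / s_step + 1e-9)) + 1
    grid = s_min + s_step * np.arange(n)
    if grid.size == 0:
        raise ValueError("empty sparsity grid")
    return grid


def sparsity_series(matrix: SimilarityMatrix, s_min: float = 0.05,
                    s_max: float = 0.39, s_step: float = 0.02) -> list[BinaryNetwork]:
    """Binarize one similarity matrix at every level of the sparsity grid."""
    return [binarize_at_sparsity(matrix, s) for s in sparsity_grid(s_min, s_max, s_step)]
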