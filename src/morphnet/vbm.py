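"""Voxelwise group inference on gray-matter maps.

Mass-univariate GLM at every in-mask voxel — a one-way group F, optionally a
partial F adjusted for nuisance covariates — followed by Benjamini-Hochberg
FDR over the in-mask p-values, a cluster-extent filter (connected components
strictly larger than a minimum size, 18-connectivity by default), peak
reporting in world (mm) coordinates, and post-hoc pooled t-tests on the
per-subject mean GM value within each surviving cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import GMMap
from .stats import (GroupDesign, StatResult, fdr_bh, partial_f_group,
                    posthoc_bonferroni, resolve_covariates)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Voxelwise statistic and p-value volumes with their analysis mask."""

    stat_values: np.ndarray
    p_values: np.ndarray
    df: tuple[float, float]
    mask: np.ndarray
    affine: np.ndarray
    stat_name: str = "F"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        inmask = self.p_values[self.mask]
        if inmask.size and (np.nanmin(inmask) < 0 or np.nanmax(inmask) > 1):
            raise ValueError("in-mask p-values must lie in [0, 1]")


@dataclass
class Cluster:
    cluster_id: int
    voxels: np.ndarray  # (k, 3) integer indices
    size: int
    peak_stat: float
    peak_voxel: tuple[int, int, int]
    peak_mm: tuple[float, float, float]


@dataclass
class ClusterSet:
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def analysis_mask(maps: list[GMMap], gm_threshold: float = 0.1,
                  subject_fraction: float = 0.9) -> np.ndarray:
    """Voxels exceeding ``gm_threshold`` in at least ``subject_fraction`` of
    subjects — the default whole-brain analysis mask."""
    stack = np.stack([m.values for m in maps])
    frac = (stack > gm_threshold).mean(axis=0)
    return frac >= subject_fraction


def voxelwise_anova(maps: list[GMMap], design: GroupDesign,
                    covariate_names: list[str] | None = None,
                    mask: np.ndarray | None = None,
                    covariate_policy: str = "drop_incomplete") -> StatMap:
    """Per-voxel partial F for the group factor over all in-mask voxels.

    All voxels share one design matrix, so the model is fit to every voxel in
    a single vectorized pass.  df = (G-1, N-G-C).
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 subjects")
    if len(maps) != len(design.table):
        raise ValueError("one map per design row required")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("all maps must share one grid")
    if mask is None:
        mask = analysis_mask(maps)
    if not mask.any():
        raise ValueError("empty analysis mask")
    data = np.stack([m.values[mask] for m in maps])  # (n, v)
    cov, _ = resolve_covariates(design, covariate_names or [], covariate_policy)
    f, p, df = partial_f_group(data, design.groups, cov)
    stat = np.full(shape, np.nan)
    pvol = np.full(shape, np.nan)
    stat[mask] = f
    pvol[mask] = p
    return StatMap(stat_values=stat, p_values=pvol,
                   df=(float(df[0]), float(df[1])), mask=mask,
                   affine=maps[0].affine, stat_name="F")


def fdr_threshold(statmap: StatMap, q: float = 0.05) -> np.ndarray:
    """BH-FDR over all in-mask p-values; True where the voxel survives."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if not statmap.mask.any():
        raise ValueError("empty mask")
    p = statmap.p_values[statmap.mask]
    reject, _ = fdr_bh(p, q)
    out = np.zeros(statmap.mask.shape, dtype=bool)
    out[statmap.mask] = reject
    return out


def cluster_filter(binary_map: np.ndarray, min_size: int = 30,
                   statmap: StatMap | None = None,
                   connectivity: int = 18) -> ClusterSet:
    """Connected components of a suprathreshold map, keeping those with size
    strictly greater than ``min_size``.

    Peak metadata (max statistic, voxel and mm coordinates) is filled from
    ``statmap`` when given.  Connectivity 6/18/26; 18 (faces + edges) is the
    default.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    labeled, n_comp = ndimage.label(np.asarray(binary_map, dtype=bool),
                                    structure=_STRUCTURES[connectivity])
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        vox = np.argwhere(labeled == comp)
        if vox.shape[0] <= min_size:
            continue
        if statmap is not None:
            vals = statmap.stat_values[tuple(vox.T)]
            k = int(np.nanargmax(vals))
            peak_stat = float(vals[k])
            affine = statmap.affine
        else:
            k, peak_stat, affine = 0, float("nan"), np.eye(4)
        pv = vox[k]
        mm = affine @ np.array([pv[0], pv[1], pv[2], 1.0])
        clusters.append(Cluster(
            cluster_id=len(clusters) + 1, voxels=vox, size=int(vox.shape[0]),
            peak_stat=peak_stat, peak_voxel=tuple(int(v) for v in pv),
            peak_mm=tuple(float(x) for x in mm[:3])))
    clusters.sort(key=lambda c: -c.size)
    for i, c in enumerate(clusters):
        c.cluster_id = i + 1
    return ClusterSet(clusters=clusters)


def cluster_mean_gmv(maps: list[GMMap], cluster: Cluster) -> np.ndarray:
    """Per-subject mean GM value within one cluster."""
    idx = tuple(cluster.voxels.T)
    return np.array([m.values[idx].mean() for m in maps])


def posthoc_cluster_tests(cluster_means: np.ndarray,
                          design: GroupDesign) -> list[StatResult]:
    """Pairwise pooled t-tests (Bonferroni) on a cluster's per-subject means."""
    return posthoc_bonferroni(cluster_means, design)
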