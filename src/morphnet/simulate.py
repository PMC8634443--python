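"""Synthetic three-group cohorts with known ground truth.

The generator emulates the study design this pipeline targets: healthy
controls (HC), non-violent schizophrenia (NSZ) and violent schizophrenia
(VSZ), default sizes 22/23/18.  Three planted effects drive every recovery
test:

* a regional atrophy gradient — one parcel's gray-matter mean is scaled by
  1 - atrophy_effect x severity, where severity averages 0/1/2 in HC/NSZ/VSZ,
  so group means fall HC > NSZ > VSZ in that parcel only;
* a topology gradient — each subject's network is a Watts-Strogatz graph
  whose rewiring probability increases with severity (0.05/0.15/0.30 group
  levels), raising global efficiency and shortening path length from HC to
  VSZ; one designated node additionally loses edges in proportion to
  severity, planting a nodal-degree effect;
* clinical coupling — patient PANSS, MOAS and illness duration are linear in
  the same latent severity (plus noise), calibrated to the demographic
  summary the analysis reproduces, so gray matter and nodal degree correlate
  negatively, and global efficiency positively, with symptom/aggression
  scores.

A single per-subject latent severity links the image-level and network-level
generators, so cross-domain correlation tests have coherent ground truth.
Everything is deterministic given the CohortSpec (including its seed), and the
returned GroundTruth records every planted parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .images import AtlasParcellation, GMMap, RegionalSamples, aal90_region_table
from .network import BinaryNetwork
from .stats import GroupDesign

#: Demographic/clinical summary used to calibrate the generated scores
#: (per group: mean, sd); sizes follow the default 22/23/18 design.
CLINICAL_CALIBRATION = {
    "duration": {"NSZ": (16.1, 28.88), "VSZ": (59.89, 65.25)},
    "PANSS": {"NSZ": (86.3, 16.49), "VSZ": (112.0, 7.4)},
    "MOAS": {"NSZ": (14.96, 3.99), "VSZ": (29.0, 3.33)},
}

GROUP_SEVERITY = {"HC": 0.0, "NSZ": 1.0, "VSZ": 2.0}


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort; the defaults are the study conditions."""

    n_per_group: tuple[int, int, int] = (22, 23, 18)  # HC, NSZ, VSZ
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    n_regions: int = 90
    planted_region_id: int | None = None  # None: largest region at generation
    atrophy_effect: float = 0.10  # fractional GM loss per severity unit
    region_mean_range: tuple[float, float] = (0.4, 0.7)
    noise_sd: float = 0.10  # voxel noise, GM units
    severity_sd: float = 0.30  # within-group spread of latent severity
    ws_degree: int = 8
    ws_rewire_p: dict = field(default_factory=lambda:
                              {"HC": 0.05, "NSZ": 0.15, "VSZ": 0.30})
    ws_p_slope: float = 0.10  # rewiring-probability change per severity unit
    degree_coupling: float = 1.5  # edges removed from the planted node per unit
    clinical_coupling: float = 0.7  # severity-score correlation within group
    clinical_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.ws_rewire_p) != {"HC", "NSZ", "VSZ"}:
            raise ValueError("ws_rewire_p must name all three groups")
        if self.ws_degree % 2 or self.ws_degree >= self.n_regions:
            raise ValueError("ws_degree must be even and < n_regions")
        nvox = int(np.prod(self.grid_shape))
        if self.n_regions > nvox / 20:
            raise ValueError("infeasible region count for this grid")


@dataclass
class GroundTruth:
    """Every planted parameter, sufficient to score recovery without
    re-running the generator."""

    seed: int
    group: list[str]
    severity: np.ndarray
    region_means: dict[int, float] | None = None
    planted_region_id: int | None = None
    atrophy_effect: float = 0.0
    n_truncated_voxels: int = 0
    ws_p: np.ndarray | None = None
    planted_node: int | None = None
    planted_node_degree: np.ndarray | None = None
    clinical_coupling: float = 0.0
    couple_signs: dict = field(default_factory=lambda: {
        "gmv_vs_PANSS": -1, "gmv_vs_MOAS": -1,
        "degree_vs_PANSS": -1, "degree_vs_MOAS": -1,
        "Eg_vs_MOAS": +1, "Lp_vs_MOAS": -1,
    })


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def generate_atlas(grid_shape: tuple[int, int, int] = (32, 32, 32),
                   n_regions: int = 90, seed: int = 0,
                   voxel_size_mm: float = 2.0,
                   min_region_voxels: int = 20) -> AtlasParcellation:
    """Voronoi-style parcellation of a spherical 'brain' mask.

    Random centers inside the mask partition its voxels by nearest center;
    center draws are rejected until every region owns at least
    ``min_region_voxels`` voxels.  Deterministic given the seed.
    """
    nvox = int(np.prod(grid_shape))
    if n_regions > nvox / 20:
        raise ValueError("infeasible region count for this grid")
    rng = _rng(seed, 101)
    shape = np.array(grid_shape)
    center = (shape - 1) / 2.0
    radius = shape.min() * 0.45
    idx = np.indices(grid_shape).reshape(3, -1).T.astype(np.float64)
    inside = ((idx - center) ** 2).sum(axis=1) <= radius**2
    coords = idx[inside]
    labels_flat = None
    for _ in range(100):
        centers = coords[rng.choice(len(coords), size=n_regions, replace=False)]
        assign = np.argmin(cdist(coords, centers), axis=1)
        counts = np.bincount(assign, minlength=n_regions)
        if counts.min() >= min_region_voxels:
            labels_flat = assign + 1
            break
    if labels_flat is None:
        raise ValueError("could not place regions with the size floor; "
                         "reduce n_regions or enlarge the grid")
    labels = np.zeros(nvox, dtype=np.int32)
    labels[inside] = labels_flat
    labels = labels.reshape(grid_shape)
    if n_regions == 90:
        regions = aal90_region_table()
    else:
        regions = pd.DataFrame({
            "region_id": np.arange(1, n_regions + 1),
            "region_name": [f"R{i:03d}" for i in range(1, n_regions + 1)]})
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -center * voxel_size_mm
    return AtlasParcellation(labels=labels, regions=regions, affine=affine)


def generate_design(spec: CohortSpec) -> tuple[GroupDesign, np.ndarray]:
    """Subject table plus the shared latent severity vector (HC exactly 0)."""
    rng = _rng(spec.seed, 202)
    groups, sev = [], []
    for g, n in zip(("HC", "NSZ", "VSZ"), spec.n_per_group):
        groups += [g] * n
        if g == "HC":
            sev += [0.0] * n
        else:
            sev += list(np.clip(
                rng.normal(GROUP_SEVERITY[g], spec.severity_sd, size=n), 0.05, None))
    table = pd.DataFrame({
        "subject_id": [f"S{i+1:03d}" for i in range(len(groups))],
        "group": groups,
        "duration": np.nan, "PANSS": np.nan, "MOAS": np.nan,
    })
    return GroupDesign(table, require_patient_clinical=False), np.array(sev)


def generate_gm_cohort(spec: CohortSpec,
                       atlas: AtlasParcellation | None = None
                       ) -> tuple[list[GMMap], GroupDesign, GroundTruth]:
    """Parcellated GM images with the planted atrophy gradient.

    Voxels of region r for subject s are Normal(mu_r * g_sr, noise_sd^2)
    truncated at 0, with g_sr = 1 everywhere except the planted region,
    where g_sr = 1 - atrophy_effect * severity_s.
    """
    if atlas is None:
        atlas = generate_atlas(spec.grid_shape, spec.n_regions, spec.seed,
                               spec.voxel_size_mm)
    design, severity = generate_design(spec)
    rng = _rng(spec.seed, 303)
    ids = atlas.region_ids
    mu = dict(zip((int(i) for i in ids),
                  rng.uniform(*spec.region_mean_range, size=len(ids))))
    counts = {int(i): int((atlas.labels == i).sum()) for i in ids}
    planted = (int(spec.planted_region_id) if spec.planted_region_id is not None
               else max(counts, key=counts.get))
    if planted not in counts:
        raise ValueError(f"planted region {planted} not in the atlas")
    base = np.zeros(spec.grid_shape)
    for rid in counts:
        base[atlas.labels == rid] = mu[rid]
    planted_mask = atlas.labels == planted
    maps, n_trunc = [], 0
    for row, sev in zip(design.table.itertuples(), severity):
        vol = base.copy()
        vol[planted_mask] = mu[planted] * max(1.0 - spec.atrophy_effect * sev, 0.05)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        vol[atlas.labels == 0] = 0.0
        n_trunc += int((vol < 0).sum())
        np.clip(vol, 0.0, None, out=vol)
        maps.append(GMMap(subject_id=row.subject_id, values=vol,
                          affine=atlas.affine.copy(), space_tag="synthetic"))
    truth = GroundTruth(seed=spec.seed, group=list(design.groups),
                        severity=severity, region_means=mu,
                        planted_region_id=planted,
                        atrophy_effect=spec.atrophy_effect,
                        n_truncated_voxels=n_trunc,
                        clinical_coupling=spec.clinical_coupling)
    design = generate_clinical_scores(design, truth,
                                      coupling=spec.clinical_coupling,
                                      noise=spec.clinical_noise, seed=spec.seed)
    return maps, design, truth


def generate_network_cohort(spec: CohortSpec
                            ) -> tuple[list[BinaryNetwork], GroupDesign, GroundTruth]:
    """Per-subject Watts-Strogatz networks with the planted topology gradient.

    Each subject's rewiring probability is the group level shifted by
    ws_p_slope x (severity - group mean); the planted node then loses
    round(degree_coupling x severity) edges, re-inserted elsewhere so the
    edge count n_regions x ws_degree / 2 is preserved.
    """
    design, severity = generate_design(spec)
    rng = _rng(spec.seed, 404)
    nets, ps, node_deg = [], [], []
    planted_node = 0
    n, k = spec.n_regions, spec.ws_degree
    for i, (row, sev) in enumerate(zip(design.table.itertuples(), severity)):
        g_lab = row.group
        p = spec.ws_rewire_p[g_lab] + spec.ws_p_slope * (sev - GROUP_SEVERITY[g_lab])
        p = float(np.clip(p, 0.0, 0.95))
        gseed = int(rng.integers(0, 2**31 - 1))
        g = nx.watts_strogatz_graph(n, k, p, seed=gseed)
        n_remove = int(np.round(spec.degree_coupling * sev))
        n_remove = min(n_remove, max(g.degree(planted_node) - 1, 0))
        for _ in range(n_remove):
            nbrs = list(g.neighbors(planted_node))
            u = nbrs[int(rng.integers(len(nbrs)))]
            g.remove_edge(planted_node, u)
            while True:  # re-insert elsewhere, keeping the graph simple
                a, b = rng.integers(1, n, size=2)
                if a != b and not g.has_edge(int(a), int(b)):
                    g.add_edge(int(a), int(b))
                    break
        adj = nx.to_numpy_array(g, nodelist=range(n)).astype(bool)
        nets.append(BinaryNetwork(adjacency=adj,
                                  sparsity=k / (n - 1),
                                  region_ids=list(range(1, n + 1)),
                                  subject_id=row.subject_id))
        ps.append(p)
        node_deg.append(int(adj[planted_node].sum()))
    truth = GroundTruth(seed=spec.seed, group=list(design.groups),
                        severity=severity, ws_p=np.array(ps),
                        planted_node=planted_node,
                        planted_node_degree=np.array(node_deg),
                        clinical_coupling=spec.clinical_coupling)
    design = generate_clinical_scores(design, truth,
                                      coupling=spec.clinical_coupling,
                                      noise=spec.clinical_noise, seed=spec.seed)
    return nets, design, truth


def generate_clinical_scores(design: GroupDesign, truth: GroundTruth,
                             coupling: float = 0.7, noise: float = 1.0,
                             seed: int = 0) -> GroupDesign:
    """Fill patient PANSS, MOAS and duration, coupled to the latent severity.

    Within each patient group the score is mean_g + sd_g x u, where u is the
    group-standardized composite w z + sqrt(1-w^2) x noise x e (z the
    group-standardized severity, w the coupling, e standard normal) — so
    group means and SDs match the calibration table exactly (durations are
    additionally truncated at 0) while scores track severity.  Severity rises with atrophy and
    rewiring, hence gray matter couples negatively and global efficiency
    positively with the scores.  HC fields stay missing; durations are
    truncated at 0.
    """
    rng = _rng(seed, 505)
    table = design.table.copy()
    groups = table["group"].to_numpy()
    sev = np.asarray(truth.severity, dtype=np.float64)
    if sev.shape[0] != len(table):
        raise ValueError("severity vector does not match the design")
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [-1, 1]")
    for score, per_group in CLINICAL_CALIBRATION.items():
        vals = np.full(len(table), np.nan)
        for g_lab, (m, s) in per_group.items():
            sel = groups == g_lab
            z = sev[sel] - sev[sel].mean()
            z = z / z.std(ddof=0) if z.std(ddof=0) > 0 else z * 0.0
            e = rng.standard_normal(sel.sum())
            comp = coupling * z + np.sqrt(1.0 - coupling**2) * noise * e
            if comp.std(ddof=0) > 0:  # group mean/SD then match exactly
                comp = (comp - comp.mean()) / comp.std(ddof=0)
            vals[sel] = m + s * comp
        if score == "duration":
            vals = np.clip(vals, 0.0, None)
        table[score] = vals
    return GroupDesign(table)


def extract_true_regional_samples(maps: list[GMMap],
                                  atlas: AtlasParcellation
                                  ) -> list[RegionalSamples]:
    """Convenience wrapper: regional samples for every subject of a cohort."""
    from .images import extract_regional_samples
    return [extract_regional_samples(m, atlas) for m in maps]
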