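"""Stage orchestration: simulate -> extract -> network -> metrics -> stats ->
correlate, with plain-file handoffs and a reproducible run manifest.

Every stage reads its inputs from, and writes its outputs to, ``outdir`` as
NIfTI/TSV/JSON, so any stage can be re-run in isolation; the manifest records
the configuration hash, seeds and SHA-256 checksums of everything written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import images, metrics, network, simulate, stats, vbm

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "extract", "network", "metrics", "stats", "correlate"]


@dataclass
class RunConfig:
    """Every stage's parameters; round-trippable to YAML."""

    outdir: str = "morphnet_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    fwhm_mm: float = 8.0
    sparsity: dict = field(default_factory=lambda:
                           {"s_min": 0.05, "s_max": 0.39, "s_step": 0.02})
    kde: dict = field(default_factory=lambda:
                      {"n_grid": 128, "bandwidth_factor": 1.0})
    null_model: dict = field(default_factory=lambda:
                             {"n_null": 100, "n_swaps_per_edge": 10})
    stats_cfg: dict = field(default_factory=lambda:
                            {"q": 0.05, "min_cluster": 30,
                             "covariates": ["PANSS", "duration"],
                             "covariate_policy": "drop_incomplete"})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_spec(self) -> simulate.CohortSpec:
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        for key in ("n_per_group", "grid_shape"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return simulate.CohortSpec(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_cohort(out: Path):
    subjects = pd.read_csv(out / "subjects.tsv", sep="\t")
    design = stats.GroupDesign(subjects)
    atlas = images.load_atlas(out / "atlas.nii.gz", out / "regions.tsv")
    maps = [images.load_gm_map(out / "maps" / f"{sid}.nii.gz", subject_id=sid)
            for sid in subjects["subject_id"]]
    return maps, design, atlas


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order; returns the manifest."""
    stages = stages or STAGE_ORDER
    bad = set(stages) - set(STAGE_ORDER)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def require(path: str, needed_by: str, produced_by: str) -> None:
        if not (out / path).exists():
            raise FileNotFoundError(
                f"stage '{needed_by}' needs {path}, produced by stage "
                f"'{produced_by}' — run it first")

    for stage in stages:
        logger.info("stage %s", stage)
        written += _STAGE_FUNCS[stage](config, out, require)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "config": dataclasses.asdict(config),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def _stage_simulate(config: RunConfig, out: Path, require) -> list[Path]:
    spec = config.cohort_spec()
    atlas = simulate.generate_atlas(spec.grid_shape, spec.n_regions, spec.seed,
                                    spec.voxel_size_mm)
    maps, design, truth = simulate.generate_gm_cohort(spec, atlas)
    (out / "maps").mkdir(exist_ok=True)
    written = []
    for m in maps:
        p = out / "maps" / f"{m.subject_id}.nii.gz"
        images.save_gm_map(m, p)
        written.append(p)
    images.save_atlas(atlas, out / "atlas.nii.gz", out / "regions.tsv")
    design.table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    truth_dict = dataclasses.asdict(truth)
    for k, v in truth_dict.items():
        if isinstance(v, np.ndarray):
            truth_dict[k] = v.tolist()
    with open(out / "ground_truth.json", "w") as f:
        json.dump(truth_dict, f, indent=2)
    return written + [out / "atlas.nii.gz", out / "regions.tsv",
                      out / "subjects.tsv", out / "ground_truth.json"]


def _stage_extract(config: RunConfig, out: Path, require) -> list[Path]:
    require("subjects.tsv", "extract", "simulate")
    require("atlas.nii.gz", "extract", "simulate")
    maps, design, atlas = _load_cohort(out)
    samples = [images.extract_regional_samples(m, images.resample_atlas_to(atlas, m))
               for m in maps]
    table = images.region_mean_table(samples, atlas)
    p = out / "region_means.tsv"
    table.to_csv(p, sep="\t", index=False)
    return [p]


def _stage_network(config: RunConfig, out: Path, require) -> list[Path]:
    require("subjects.tsv", "network", "simulate")
    maps, design, atlas = _load_cohort(out)
    names = dict(zip(atlas.regions["region_id"], atlas.regions["region_name"]))
    (out / "networks").mkdir(exist_ok=True)
    written = []
    rows = []
    grid = network.sparsity_grid(**config.sparsity)
    for m in maps:
        rs = images.extract_regional_samples(m, images.resample_atlas_to(atlas, m))
        sim = network.build_similarity_matrix(rs, list(atlas.region_ids),
                                              **config.kde)
        df = pd.DataFrame(sim.values,
                          index=[names[r] for r in sim.region_ids],
                          columns=[names[r] for r in sim.region_ids])
        p = out / "networks" / f"{m.subject_id}_similarity.tsv"
        df.to_csv(p, sep="\t")
        written.append(p)
        for s in grid:
            net = network.binarize_at_sparsity(sim, float(s))
            iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
            for i, j in zip(iu, ju):
                rows.append((m.subject_id, float(s),
                             sim.region_ids[i], sim.region_ids[j]))
    edges = pd.DataFrame(rows, columns=["subject_id", "sparsity",
                                        "region_i", "region_j"])
    p = out / "edges.tsv"
    edges.to_csv(p, sep="\t", index=False)
    return written + [p]


def _stage_metrics(config: RunConfig, out: Path, require) -> list[Path]:
    require("edges.tsv", "metrics", "network")
    edges = pd.read_csv(out / "edges.tsv", sep="\t")
    atlas_regions = pd.read_csv(out / "regions.tsv", sep="\t")
    ids = atlas_regions["region_id"].tolist()
    pos = {r: i for i, r in enumerate(ids)}
    n = len(ids)
    long_rows, auc_rows = [], []
    nm = config.null_model
    for sid, sub in edges.groupby("subject_id", sort=False):
        records = []
        for s, se in sub.groupby("sparsity", sort=True):
            adj = np.zeros((n, n), dtype=bool)
            i = se["region_i"].map(pos).to_numpy()
            j = se["region_j"].map(pos).to_numpy()
            adj[i, j] = adj[j, i] = True
            net = network.BinaryNetwork(adjacency=adj, sparsity=float(s),
                                        region_ids=ids, subject_id=sid)
            rec = metrics.metrics_record(net, n_null=nm["n_null"],
                                         n_swaps_per_edge=nm["n_swaps_per_edge"],
                                         seed=config.seed)
            records.append(rec)
            for name in metrics.GraphMetricsRecord.GLOBAL_NAMES:
                long_rows.append((sid, float(s), name, "global",
                                  getattr(rec, name)))
            for k, rid in enumerate(ids):
                long_rows.append((sid, float(s), "degree", rid,
                                  rec.nodal_degree[k]))
                long_rows.append((sid, float(s), "betweenness", rid,
                                  rec.nodal_betweenness[k]))
        for curve in metrics.metric_curves(records):
            auc_rows.append((sid, curve.metric, curve.auc))
    long_df = pd.DataFrame(long_rows, columns=["subject_id", "sparsity",
                                               "metric", "node", "value"])
    auc_df = pd.DataFrame(auc_rows, columns=["subject_id", "metric", "auc"])
    p1, p2 = out / "metrics_long.tsv", out / "metrics_auc.tsv"
    long_df.to_csv(p1, sep="\t", index=False)
    auc_df.to_csv(p2, sep="\t", index=False)
    meta = {"seed": config.seed, **nm}
    p3 = out / "metrics_meta.json"
    with open(p3, "w") as f:
        json.dump(meta, f, indent=2)
    return [p1, p2, p3]


def _stage_stats(config: RunConfig, out: Path, require) -> list[Path]:
    require("subjects.tsv", "stats", "simulate")
    maps, design, atlas = _load_cohort(out)
    cfg = config.stats_cfg
    smoothed = [images.smooth_gm_map(m, config.fwhm_mm) for m in maps]
    statmap = vbm.voxelwise_anova(smoothed, design, cfg["covariates"],
                                  covariate_policy=cfg["covariate_policy"])
    surv = vbm.fdr_threshold(statmap, cfg["q"])
    clusters = vbm.cluster_filter(surv, cfg["min_cluster"], statmap)
    import nibabel as nib
    written = []
    for name, vol in (("stat_F", statmap.stat_values),
                      ("stat_p", statmap.p_values),
                      ("stat_mask", surv.astype(np.int16))):
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.nan_to_num(np.asarray(vol, dtype=np.float64)),
                                 statmap.affine), str(p))
        written.append(p)
    cl_rows, test_rows = [], []
    for c in clusters:
        cl_rows.append((c.cluster_id, c.size, *c.peak_mm, c.peak_stat))
        means = vbm.cluster_mean_gmv(smoothed, c)
        for r in vbm.posthoc_cluster_tests(means, design):
            test_rows.append((f"cluster{c.cluster_id}", r.comparison, r.statistic,
                              r.p_raw, r.p_adj, r.method, r.direction))
    pd.DataFrame(cl_rows, columns=["cluster_id", "size", "peak_x_mm", "peak_y_mm",
                                   "peak_z_mm", "peak_stat"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    written.append(out / "clusters.tsv")
    # group tests on AUC metric summaries when the metrics stage has run
    if (out / "metrics_auc.tsv").exists():
        auc = pd.read_csv(out / "metrics_auc.tsv", sep="\t")
        wide = auc.pivot(index="subject_id", columns="metric", values="auc")
        wide = wide.loc[design.table["subject_id"]]
        for metric_name in ("Eg", "Lp", "Cp", "Eloc", "sigma"):
            if metric_name not in wide:
                continue
            vals = wide[metric_name].to_numpy()
            if not np.all(np.isfinite(vals)):
                continue
            res = stats.ancova(vals, design, cfg["covariates"],
                               cfg["covariate_policy"])
            test_rows.append((metric_name, res.comparison, res.statistic,
                              res.p_raw, res.p_adj, res.method, res.direction))
            for r in stats.posthoc_bonferroni(vals, design):
                test_rows.append((metric_name, r.comparison, r.statistic,
                                  r.p_raw, r.p_adj, r.method, r.direction))
    pd.DataFrame(test_rows, columns=["measure", "comparison", "statistic",
                                     "p_raw", "p_adj", "method",
                                     "direction"]).to_csv(
        out / "group_stats.tsv", sep="\t", index=False)
    written.append(out / "group_stats.tsv")
    summary = {"df": statmap.df, "q": cfg["q"], "min_cluster": cfg["min_cluster"],
               "n_surviving_voxels": int(surv.sum()),
               "n_clusters": len(clusters)}
    with open(out / "vbm_summary.json", "w") as f:
        json.dump(summary, f, indent=2)
    written.append(out / "vbm_summary.json")
    return written


def _stage_correlate(config: RunConfig, out: Path, require) -> list[Path]:
    require("subjects.tsv", "correlate", "simulate")
    require("clusters.tsv", "correlate", "stats")
    subjects = pd.read_csv(out / "subjects.tsv", sep="\t")
    design = stats.GroupDesign(subjects)
    patients = design.patients().table
    measures = pd.DataFrame({"subject_id": subjects["subject_id"]})
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
    if len(clusters):
        maps, design_all, atlas = _load_cohort(out)
        smoothed = [images.smooth_gm_map(m, config.fwhm_mm) for m in maps]
        import nibabel as nib
        surv = np.asarray(nib.load(str(out / "stat_mask.nii.gz")).dataobj) > 0
        stat_f = np.asarray(nib.load(str(out / "stat_F.nii.gz")).dataobj)
        cs = vbm.cluster_filter(surv, config.stats_cfg["min_cluster"],
                                vbm.StatMap(stat_f, np.zeros_like(stat_f),
                                            (1, 1), surv,
                                            maps[0].affine))
        for c in cs:
            measures[f"cluster{c.cluster_id}_gmv"] = vbm.cluster_mean_gmv(smoothed, c)
    if (out / "metrics_auc.tsv").exists():
        auc = pd.read_csv(out / "metrics_auc.tsv", sep="\t")
        wide = auc.pivot(index="subject_id", columns="metric", values="auc")
        for mname in ("Eg", "Lp", "mean_nodal_degree"):
            if mname in wide:
                measures[mname] = wide.loc[subjects["subject_id"], mname].to_numpy()
    scores = patients[["subject_id", "duration", "PANSS", "MOAS"]]
    meas_pat = measures[measures["subject_id"].isin(patients["subject_id"])]
    results = stats.clinical_correlations(meas_pat, scores,
                                          q=config.stats_cfg["q"])
    p = out / "correlations.tsv"
    stats.results_table(results).to_csv(p, sep="\t", index=False)
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "network": _stage_network,
    "metrics": _stage_metrics,
    "stats": _stage_stats,
    "correlate": _stage_correlate,
}
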