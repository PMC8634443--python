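"""Group-level statistics: ANOVA/ANCOVA, pooled post-hoc t-tests with
Bonferroni, summary-statistic tests, clinical correlations, and BH-FDR.

Between-group tests follow the study design: a one-way F (optionally with
covariates, i.e. a partial F for the group factor adjusted for nuisance
regressors) across the three groups, then pooled-variance two-sample t-tests
for each group pair with Bonferroni adjustment.  Pooled-variance (Student)
rather than Welch t is the default because it is what summary demographic
tables of this kind report; Welch is available as an option.

Clinical correlations are Pearson by default, computed over patients only
(controls have no symptom or aggression scores), with Benjamini-Hochberg FDR
across the whole family of (measure, score) pairs in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUPS = ("HC", "NSZ", "VSZ")
CLINICAL_COLS = ("duration", "PANSS", "MOAS")


@dataclass
class GroupDesign:
    """Subject table: group membership plus clinical covariates/scores.

    ``table`` columns: subject_id, group (HC/NSZ/VSZ), duration (months),
    PANSS (total score), MOAS (aggression score).  Clinical fields may be
    missing (NaN) for HC only.
    """

    table: pd.DataFrame
    require_patient_clinical: bool = True

    def __post_init__(self) -> None:
        need = {"subject_id", "group"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(need)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for col in CLINICAL_COLS:
            if self.require_patient_clinical and col in self.table.columns:
                miss = self.table[col].isna() & (self.table["group"] != "HC")
                if miss.any():
                    who = self.table.loc[miss, "subject_id"].tolist()
                    raise ValueError(f"{col} missing for patient subjects {who}")

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    @property
    def n_per_group(self) -> dict[str, int]:
        return {g: int((self.groups == g).sum()) for g in GROUPS
                if (self.groups == g).any()}

    def patients(self) -> "GroupDesign":
        return GroupDesign(self.table[self.table["group"] != "HC"]
                           .reset_index(drop=True))


@dataclass
class StatResult:
    """One test's outcome with its multiple-comparison metadata."""

    test: str
    comparison: str
    statistic: float
    df: tuple[float, ...]
    p_raw: float
    p_adj: float
    method: str
    direction: int = 0  # sign of (first group - second group) or of r

    def __post_init__(self) -> None:
        if np.isfinite(self.p_raw) and np.isfinite(self.p_adj):
            if self.p_adj < self.p_raw - 1e-12:
                raise ValueError("adjusted p must be >= raw p")


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, monotone adjusted p)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def pooled_t_from_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int,
                          labels: tuple[str, str] = ("g1", "g2"),
                          welch: bool = False) -> StatResult:
    """Two-sample t from summary statistics (pooled variance by default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    diff = mean1 - mean2
    if welch:
        se2 = sd1**2 / n1 + sd2**2 / n2
        if se2 == 0:
            if diff != 0:
                raise ValueError("zero variance with unequal means")
            se2, df = np.nan, n1 + n2 - 2
        else:
            df = se2**2 / ((sd1**2 / n1)**2 / (n1 - 1)
                           + (sd2**2 / n2)**2 / (n2 - 1))
        se = np.sqrt(se2)
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        if sp2 == 0:
            if diff != 0:
                raise ValueError("zero pooled variance with unequal means")
            sp2 = np.nan
        df = n1 + n2 - 2
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if diff == 0:
        t, p = 0.0, 1.0
    else:
        t = diff / se
        p = 2 * sps.t.sf(abs(t), df)
    return StatResult(test="t" if not welch else "t_welch",
                      comparison=f"{labels[0]} vs {labels[1]}",
                      statistic=float(t), df=(float(df),), p_raw=float(p),
                      p_adj=float(p), method="none",
                      direction=int(np.sign(diff)))


def anova_from_summary(means: np.ndarray, sds: np.ndarray,
                       ns: np.ndarray, labels: list[str] | None = None) -> StatResult:
    """One-way F reconstructed from per-group means, SDs and sizes."""
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    ns = np.asarray(ns, dtype=np.int64)
    g = means.size
    if g < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n_tot = int(ns.sum())
    grand = float((ns * means).sum() / n_tot)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1, df2 = g - 1, n_tot - g
    if ss_within == 0:
        if ss_between > 0:
            raise ValueError("degenerate within-group variance")
        f, p = 0.0, 1.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2))
    labels = labels or [f"g{i+1}" for i in range(g)]
    return StatResult(test="F_oneway", comparison=" vs ".join(labels),
                      statistic=float(f), df=(float(df1), float(df2)),
                      p_raw=float(p), p_adj=float(p), method="none")


def _group_dummies(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = [g for g in GROUPS if (groups == g).any()]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    dum = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    return dum, levels


def partial_f_group(y: np.ndarray, groups: np.ndarray,
                    covariates: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Partial F for the group factor: full model [1 | group | covariates]
    versus the covariate-only reduced model.

    ``y`` may be (n,) or (n, v) for v simultaneous responses (voxels share
    one design, so the projections are computed once).  Returns (F, p, df)
    with df = (G-1, N-G-C).
    """
    y = np.asarray(y, dtype=np.float64)
    y2d = y.reshape(y.shape[0], -1)
    n = y2d.shape[0]
    dum, levels = _group_dummies(groups)
    g = len(levels)
    if covariates is None or covariates.size == 0:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=np.float64).reshape(n, -1)
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariates contain missing/non-finite values")
    c = cov.shape[1]
    x_full = np.column_stack([np.ones(n), dum, cov])
    x_red = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("rank-deficient design matrix")
    df1 = g - 1
    df2 = n - g - c
    if df2 <= 0:
        raise ValueError("not enough subjects for the requested model")
    rss_full = _rss(x_full, y2d)
    rss_red = _rss(x_red, y2d)
    num = np.maximum(rss_red - rss_full, 0.0) / df1
    den = rss_full / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / den, 0.0)
    p = sps.f.sf(f, df1, df2)
    p = np.where(den > 0, p, 1.0)
    f = f.reshape(y.shape[1:]) if y.ndim > 1 else float(f[0])
    p = p.reshape(y.shape[1:]) if y.ndim > 1 else float(p[0])
    return f, p, (df1, df2)


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return (resid**2).sum(axis=0)


def resolve_covariates(design: GroupDesign, covariate_names: list[str],
                       policy: str = "drop_incomplete"
                       ) -> tuple[np.ndarray | None, list[str]]:
    """Covariate matrix for the subjects in ``design`` under the missing-data
    policy.

    The study's symptom and duration covariates exist only for patients, so a
    three-group model cannot literally adjust for them.  Policies:
    ``drop_incomplete`` (default) removes any covariate with missing values
    from the model and reports which; ``mean_impute`` fills missing values
    with the observed mean; ``strict`` raises, naming the first subject with
    a missing value.
    """
    if not covariate_names:
        return None, []
    cols, kept = [], []
    for name in covariate_names:
        v = design.table[name].to_numpy(dtype=np.float64)
        if np.isnan(v).any():
            if policy == "drop_incomplete":
                continue
            if policy == "mean_impute":
                v = np.where(np.isnan(v), np.nanmean(v), v)
            else:
                who = design.table.loc[np.isnan(v), "subject_id"].iloc[0]
                raise ValueError(f"covariate {name} missing for subject {who}")
        cols.append(v)
        kept.append(name)
    if not cols:
        return None, []
    return np.column_stack(cols), kept


def ancova(values: np.ndarray, design: GroupDesign,
           covariates: list[str] | None = None,
           covariate_policy: str = "drop_incomplete") -> StatResult:
    """Group effect on a scalar measure, adjusted for covariates (partial F)."""
    values = np.asarray(values, dtype=np.float64)
    cov, kept = resolve_covariates(design, covariates or [], covariate_policy)
    f, p, df = partial_f_group(values, design.groups, cov)
    label = " vs ".join(g for g in GROUPS if (design.groups == g).any())
    method = "ancova[" + ",".join(kept) + "]" if kept else "anova"
    return StatResult(test="F_group", comparison=label, statistic=float(f),
                      df=(float(df[0]), float(df[1])), p_raw=float(p),
                      p_adj=float(p), method=method)


def posthoc_bonferroni(values: np.ndarray, design: GroupDesign,
                       welch: bool = False) -> list[StatResult]:
    """Pooled two-sample t for every group pair, Bonferroni-adjusted."""
    values = np.asarray(values, dtype=np.float64)
    groups = design.groups
    levels = [g for g in GROUPS if (groups == g).any()]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        ya, yb = values[groups == a], values[groups == b]
        if ya.size < 2 or yb.size < 2:
            raise ValueError(f"group {a if ya.size < 2 else b} has < 2 subjects")
        res = pooled_t_from_summary(ya.mean(), ya.std(ddof=1), ya.size,
                                    yb.mean(), yb.std(ddof=1), yb.size,
                                    labels=(a, b), welch=welch)
        out.append(replace(res, p_adj=min(1.0, res.p_raw * m),
                           method=f"bonferroni[{m}]"))
    return out


def clinical_correlations(measures: pd.DataFrame, scores: pd.DataFrame,
                          method: str = "pearson", q: float = 0.05
                          ) -> list[StatResult]:
    """Correlate every measure with every clinical score; BH-FDR over the family.

    Both tables are indexed by subject_id (or carry a subject_id column);
    only subjects present in both enter.  Constant vectors yield a flagged
    NaN result that is excluded from the FDR family.
    """
    measures = _indexed(measures)
    scores = _indexed(scores)
    common = measures.index.intersection(scores.index)
    results: list[StatResult] = []
    pvals, idx = [], []
    for mcol in measures.columns:
        for scol in scores.columns:
            sub = pd.concat([measures.loc[common, mcol],
                             scores.loc[common, scol]], axis=1).dropna()
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            comp = f"{mcol} vs {scol}"
            if len(sub) < 3:
                raise ValueError(f"{comp}: need >= 3 complete pairs")
            if np.std(x) == 0 or np.std(y) == 0:
                results.append(StatResult(test=method, comparison=comp,
                                          statistic=float("nan"), df=(len(sub) - 2,),
                                          p_raw=float("nan"), p_adj=float("nan"),
                                          method="flagged:constant"))
                continue
            if method == "pearson":
                r, p = sps.pearsonr(x, y)
            elif method == "spearman":
                r, p = sps.spearmanr(x, y)
            else:
                raise ValueError(f"unknown correlation method {method!r}")
            idx.append(len(results))
            pvals.append(p)
            results.append(StatResult(test=method, comparison=comp,
                                      statistic=float(r), df=(len(sub) - 2,),
                                      p_raw=float(p), p_adj=float(p),
                                      method="pending", direction=int(np.sign(r))))
    if pvals:
        _, p_adj = fdr_bh(np.array(pvals), q)
        for k, i in enumerate(idx):
            results[i] = replace(results[i], p_adj=float(p_adj[k]),
                                 method=f"fdr_bh[{len(pvals)}]")
    return results


def _indexed(df: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" in df.columns:
        return df.set_index("subject_id")
    return df


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Flatten StatResults into the standard output TSV layout."""
    return pd.DataFrame([{
        "test": r.test, "comparison": r.comparison, "statistic": r.statistic,
        "df": "/".join(f"{d:g}" for d in r.df), "p_raw": r.p_raw,
        "p_adj": r.p_adj, "method": r.method, "direction": r.direction,
    } for r in results])
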