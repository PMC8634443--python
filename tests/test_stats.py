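"""Group-level statistics: summary tests, ANCOVA, post-hoc, FDR, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from morphnet.stats import (GroupDesign, ancova, anova_from_summary,
                            clinical_correlations, fdr_bh, partial_f_group,
                            pooled_t_from_summary, posthoc_bonferroni)


def _design(n_hc=6, n_nsz=6, n_vsz=6, seed=0):
    rng = np.random.default_rng(seed)
    groups = ["HC"] * n_hc + ["NSZ"] * n_nsz + ["VSZ"] * n_vsz
    n = len(groups)
    table = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "group": groups,
        "duration": np.where(np.array(groups) == "HC", np.nan,
                             rng.uniform(5, 80, n)),
        "PANSS": np.where(np.array(groups) == "HC", np.nan,
                          rng.uniform(60, 120, n)),
        "MOAS": np.where(np.array(groups) == "HC", np.nan,
                         rng.uniform(5, 30, n)),
    })
    return GroupDesign(table)


class TestSummaryTests:
    def test_equal_means_t_zero(self):
        r = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_t_squared_equals_two_group_f(self):
        r_t = pooled_t_from_summary(3.1, 1.2, 14, 2.4, 0.9, 11)
        r_f = anova_from_summary([3.1, 2.4], [1.2, 0.9], [14, 11])
        assert r_t.statistic**2 == pytest.approx(r_f.statistic, abs=1e-10)
        assert r_t.p_raw == pytest.approx(r_f.p_raw, abs=1e-10)

    def test_summary_anova_matches_raw_data_anova(self):
        rng = np.random.default_rng(1)
        gs = [rng.normal(m, 1.0, n) for m, n in ((0.0, 8), (0.5, 10), (1.0, 7))]
        res = anova_from_summary([g.mean() for g in gs],
                                 [g.std(ddof=1) for g in gs],
                                 [len(g) for g in gs])
        f_ref, p_ref = sps.f_oneway(*gs)
        assert res.statistic == pytest.approx(f_ref, abs=1e-10)
        assert res.p_raw == pytest.approx(p_ref, abs=1e-10)

    def test_all_equal_group_means_f_zero(self):
        r = anova_from_summary([2.0, 2.0, 2.0], [1.0, 1.5, 0.5], [5, 5, 5])
        assert r.statistic == 0.0

    def test_zero_pooled_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_welch_option_differs_from_pooled(self):
        pooled = pooled_t_from_summary(59.89, 65.25, 18, 16.1, 28.88, 23)
        welch = pooled_t_from_summary(59.89, 65.25, 18, 16.1, 28.88, 23,
                                      welch=True)
        assert pooled.statistic == pytest.approx(2.88, abs=0.01)
        assert welch.statistic == pytest.approx(2.65, abs=0.05)


class TestAncova:
    def test_no_covariates_reduces_to_anova(self):
        rng = np.random.default_rng(2)
        d = _design(8, 8, 8)
        y = rng.normal(0, 1, 24)
        res = ancova(y, d, [])
        groups = d.groups
        f_ref, p_ref = sps.f_oneway(*(y[groups == g] for g in ("HC", "NSZ", "VSZ")))
        assert res.statistic == pytest.approx(f_ref, abs=1e-10)

    def test_confound_mediated_effect_vanishes_when_adjusted(self):
        """If the group effect is carried entirely by the covariate, the
        partial F is small while the unadjusted F is large."""
        rng = np.random.default_rng(3)
        groups = np.repeat(["HC", "NSZ", "VSZ"], 20)
        cov = np.repeat([0.0, 1.0, 2.0], 20) + rng.normal(0, 0.3, 60)
        y = 2.0 * cov + rng.normal(0, 0.3, 60)
        f_adj, _, _ = partial_f_group(y, groups, cov.reshape(-1, 1))
        f_raw, _, _ = partial_f_group(y, groups, None)
        assert f_raw > 50
        assert f_adj < f_raw / 10

    def test_missing_covariate_policies(self):
        d = _design()
        y = np.arange(18.0)
        res_drop = ancova(y, d, ["PANSS"], covariate_policy="drop_incomplete")
        assert res_drop.method == "anova"  # PANSS undefined for HC, dropped
        res_imp = ancova(y, d, ["PANSS"], covariate_policy="mean_impute")
        assert "PANSS" in res_imp.method
        with pytest.raises(ValueError, match="S000"):
            ancova(y, d, ["PANSS"], covariate_policy="strict")

    def test_rank_deficient_design_rejected(self):
        d = _design()
        cov = (d.groups == "NSZ").astype(float) + (d.groups == "VSZ") * 2.0
        d.table["duration"] = cov  # collinear with group dummies
        with pytest.raises(ValueError, match="rank"):
            ancova(np.arange(18.0), d, ["duration"], covariate_policy="strict")

    def test_df_accounts_for_covariates(self):
        d = _design()
        res = ancova(np.random.default_rng(4).normal(size=18), d,
                     ["PANSS", "duration"], covariate_policy="mean_impute")
        assert res.df == (2.0, 18 - 3 - 2)


class TestPosthoc:
    def test_three_groups_three_comparisons_multiplier_three(self):
        d = _design()
        rng = np.random.default_rng(5)
        res = posthoc_bonferroni(rng.normal(0, 1, 18), d)
        assert len(res) == 3
        for r in res:
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * 3))

    def test_identical_groups_t_zero_p_one(self):
        d = _design(4, 4, 4)
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        for r in posthoc_bonferroni(vals, d):
            assert r.statistic == 0.0 and r.p_adj == 1.0

    def test_small_group_rejected(self):
        d = _design(1, 6, 6)
        with pytest.raises(ValueError, match="HC"):
            posthoc_bonferroni(np.arange(13.0), d)


class TestFdrBH:
    def test_hand_applied_step_up_all_rejected(self):
        reject, _ = fdr_bh(np.array([0.01, 0.04, 0.03, 0.005]), 0.05)
        assert reject.all()

    def test_hand_applied_partial_rejection(self):
        # thresholds (k/4)*0.05: 0.0125, 0.025, 0.0375, 0.05
        reject, _ = fdr_bh(np.array([0.001, 0.002, 0.9, 0.95]), 0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fdr_bh(np.array([0.049]), 0.05)
        assert reject[0]

    def test_extremes(self):
        assert fdr_bh(np.ones(5), 0.05)[0].sum() == 0
        assert fdr_bh(np.zeros(5), 0.05)[0].all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_adjusted_p_monotone_and_survival_nested(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 25)
        rej1, p_adj = fdr_bh(p, 0.01)
        rej5, _ = fdr_bh(p, 0.05)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-15)
        assert np.all(rej5[rej1])  # survival at q=0.01 subset of q=0.05
        assert np.all(p_adj >= p - 1e-15)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([]), 0.05)


class TestClinicalCorrelations:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 1, 20)
        meas = pd.DataFrame({"subject_id": range(20), "m": x})
        scores = pd.DataFrame({"subject_id": range(20), "s": 2 * x + 1})
        (r,) = clinical_correlations(meas, scores)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_raw < 1e-10

    def test_constant_vector_flagged_and_excluded_from_family(self):
        rng = np.random.default_rng(6)
        meas = pd.DataFrame({"subject_id": range(10),
                             "ok": rng.normal(size=10),
                             "const": np.ones(10)})
        scores = pd.DataFrame({"subject_id": range(10),
                               "s": rng.normal(size=10)})
        res = {r.comparison: r for r in clinical_correlations(meas, scores)}
        assert np.isnan(res["const vs s"].statistic)
        assert res["const vs s"].method == "flagged:constant"
        assert res["ok vs s"].method == "fdr_bh[1]"  # family of one

    def test_too_few_pairs_rejected(self):
        meas = pd.DataFrame({"subject_id": [1, 2], "m": [0.1, 0.2]})
        scores = pd.DataFrame({"subject_id": [1, 2], "s": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 complete"):
            clinical_correlations(meas, scores)

    def test_all_null_fdr_calibration(self):
        """Under a fully null family BH attains FDR ~ q; the mean FDP over
        many families should sit near 0.05 (two-sided check)."""
        rng = np.random.default_rng(7)
        fdps = []
        for _ in range(1000):
            p = np.array([sps.pearsonr(rng.standard_normal(40),
                                       rng.standard_normal(40)).pvalue
                          for _ in range(8)])
            reject, _ = fdr_bh(p, 0.05)
            fdps.append(1.0 if reject.any() else 0.0)
        assert 0.03 <= np.mean(fdps) <= 0.07


class TestGroupDesign:
    def test_patient_missing_clinical_rejected(self):
        table = pd.DataFrame({"subject_id": ["a", "b"], "group": ["HC", "NSZ"],
                              "duration": [np.nan, np.nan],
                              "PANSS": [np.nan, 90.0], "MOAS": [np.nan, 10.0]})
        with pytest.raises(ValueError, match="duration"):
            GroupDesign(table)

    def test_hc_missing_clinical_allowed_and_patients_subset(self):
        d = _design(3, 3, 3)
        assert d.n_per_group == {"HC": 3, "NSZ": 3, "VSZ": 3}
        assert set(d.patients().table["group"]) == {"NSZ", "VSZ"}

    def test_unknown_group_rejected(self):
        table = pd.DataFrame({"subject_id": ["a"], "group": ["XX"]})
        with pytest.raises(ValueError, match="XX"):
            GroupDesign(table)
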