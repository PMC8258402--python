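"""Cohort statistics: ANCOVA, partial Spearman, chi-square, Bonferroni, ICC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lsamorph import (
    EffectConfig,
    adjusted_group_compare,
    bonferroni,
    chi_square,
    generate_cohort,
    icc_consistency,
    rank_correlation,
    run_full_analysis,
    study_effect_config,
)


class TestAdjustedGroupCompare:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        half = pd.DataFrame({
            "y": rng.normal(size=30), "age": rng.normal(60, 5, 30),
            "sex": rng.integers(0, 2, 30), "icv": rng.normal(1450, 100, 30),
        })
        # duplicate every subject into both groups: perfectly symmetric
        table = pd.concat([half.assign(g=0), half.assign(g=1)],
                          ignore_index=True)
        res = adjusted_group_compare(table, "y", "g")
        assert res.effect == pytest.approx(0.0, abs=1e-10)
        assert res.p_raw == pytest.approx(1.0, abs=1e-9)
        assert res.n == 60

    def test_reduces_to_oneway_anova_without_covariates(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"y": rng.normal(size=80),
                              "g": rng.integers(0, 2, 80)})
        res = adjusted_group_compare(table, "y", "g", covariates=())
        f, p = sps.f_oneway(table.y[table.g == 0], table.y[table.g == 1])
        assert res.statistic == pytest.approx(f, abs=1e-6)
        assert res.p_raw == pytest.approx(p, abs=1e-9)

    def test_covariate_confounding_is_removed(self):
        # outcome depends only on age; group is older on average
        rng = np.random.default_rng(2)
        n = 400
        g = rng.integers(0, 2, n)
        age = 60 + 5 * g + rng.normal(0, 3, n)
        y = 2.0 * age + rng.normal(0, 1, n)
        table = pd.DataFrame({"y": y, "g": g, "age": age,
                              "sex": rng.integers(0, 2, n),
                              "icv": rng.normal(1450, 100, n)})
        res = adjusted_group_compare(table, "y", "g")
        assert abs(res.effect) < 0.5        # raw gap would be ~10
        unadjusted = adjusted_group_compare(table, "y", "g", covariates=())
        assert abs(unadjusted.effect) > 5

    def test_listwise_deletion_reports_n(self):
        t = generate_cohort(EffectConfig(seed=0)).copy()
        t.loc[t.index[:10], "icv"] = np.nan
        res = adjusted_group_compare(t, "median_vl", "smoking")
        assert res.n == 115

    def test_errors(self):
        t = generate_cohort(EffectConfig(seed=0)).copy()
        with pytest.raises(KeyError, match="nope"):
            adjusted_group_compare(t, "nope", "smoking")
        t["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            adjusted_group_compare(t, "flat", "smoking")
        t["empty_group"] = 0
        with pytest.raises(ValueError, match=">= 2 subjects"):
            adjusted_group_compare(t, "median_vl", "empty_group")


class TestRankCorrelation:
    def test_monotone_relation_gives_one(self):
        table = pd.DataFrame({"x": np.arange(20.0),
                              "y": np.exp(np.arange(20.0) / 5)})
        res = rank_correlation(table, "x", "y", covariates=())
        assert res.effect == pytest.approx(1.0)
        assert res.p_raw < 1e-10

    def test_independence_gives_near_zero(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x": rng.normal(size=5000),
                              "y": rng.normal(size=5000)})
        res = rank_correlation(table, "x", "y", covariates=())
        assert abs(res.effect) < 0.05

    def test_matches_classical_spearman_exactly(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"x": rng.normal(size=60),
                              "y": rng.normal(size=60)})
        res = rank_correlation(table, "x", "y", covariates=())
        ref = sps.spearmanr(table.x, table.y)
        assert res.effect == pytest.approx(ref.statistic, abs=1e-12)

    def test_matches_pingouin_partial_spearman(self):
        pingouin = pytest.importorskip("pingouin")
        t = generate_cohort(study_effect_config(seed=11))
        res = rank_correlation(t, "pca_diameter_mm", "median_vl")
        ref = pingouin.partial_corr(t, x="pca_diameter_mm", y="median_vl",
                                    covar=["age", "sex", "icv"],
                                    method="spearman")
        assert res.effect == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_copula_target_recovered(self):
        cfg = EffectConfig(n_subjects=10000, seed=6,
                           diameter_correlations={("pca", "median_vl"): 0.3})
        t = generate_cohort(cfg)
        res = rank_correlation(t, "pca_diameter_mm", "median_vl",
                               covariates=())
        assert res.effect == pytest.approx(0.3, abs=0.03)

    def test_constant_variable_rejected(self):
        table = pd.DataFrame({"x": [1.0] * 10, "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            rank_correlation(table, "x", "y", covariates=())


class TestChiSquare:
    def test_balanced_table_is_null(self):
        table = pd.DataFrame({
            "a": [0] * 50 + [1] * 50,
            "b": ([0] * 25 + [1] * 25) * 2,
        })
        res = chi_square(table, "a", "b")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_perfect_association(self):
        table = pd.DataFrame({"a": [0] * 50 + [1] * 50,
                              "b": [0] * 50 + [1] * 50})
        res = chi_square(table, "a", "b")
        assert res.p_raw < 1e-20
        assert res.effect == pytest.approx(1.0)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_seeds = 400
        for _ in range(n_seeds):
            table = pd.DataFrame({"a": rng.integers(0, 2, 125),
                                  "b": rng.integers(0, 2, 125)})
            if chi_square(table, "a", "b").p_raw < 0.05:
                rejections += 1
        assert 0.02 < rejections / n_seeds < 0.08

    def test_degenerate_margin_rejected(self):
        table = pd.DataFrame({"a": [0] * 10, "b": [0, 1] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            chi_square(table, "a", "b")


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], m=5) == [0.05]
        assert bonferroni([0.5], m=10) == [1.0]
        assert bonferroni([0.2, 0.7], m=1) == [0.2, 0.7]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_monotone_and_order_preserving(self, pvals):
        adj = bonferroni(pvals)
        assert len(adj) == len(pvals)
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-15).all()


class TestICC:
    def test_identical_measurements(self):
        a = np.random.default_rng(0).normal(3.0, 0.4, 30)
        assert icc_consistency(a, a) == pytest.approx(1.0)

    def test_independent_noise_drives_icc_down(self):
        rng = np.random.default_rng(1)
        a = rng.normal(3.0, 0.4, 200)
        b = a + rng.normal(0, 4.0, 200)
        assert abs(icc_consistency(a, b)) < 0.2

    def test_constant_offset_penalized(self):
        # absolute agreement: a systematic shift lowers the ICC even
        # though the rank order is perfect
        a = np.array([1.0, 2.0, 3.0])
        icc = icc_consistency(a, a + 1.0)
        # closed form for this 3-subject table: MSR = 2, MSC = 1.5,
        # MSE = 0 -> ICC = 2 / (2 + 2*1.5/3) = 2/3
        assert icc == pytest.approx(2.0 / 3.0)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = rng.normal(3.0, 0.5, 30)
        b = a + rng.normal(0, 0.2, 30) + 0.1
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile(["r1", "r2"], 30),
            "score": np.column_stack([a, b]).ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject",
                                       raters="rater", ratings="score")
        icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_consistency(a, b) == pytest.approx(icc2, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_consistency([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestFullAnalysis:
    def test_grid_shape_and_families(self):
        results = run_full_analysis(generate_cohort(EffectConfig(seed=0)))
        assert len(results) == 4 * 4 + 5 * 7
        families = {r.family for r in results}
        assert families == {"risk_factors", "diameters"}
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * (
                16 if r.family == "risk_factors" else 35)))

    def test_null_cohort_rarely_family_significant(self):
        hits = 0
        for s in range(40):
            results = run_full_analysis(generate_cohort(EffectConfig(seed=s)))
            if any(r.p_adjusted < 0.05 for r in results):
                hits += 1
        assert hits <= 8       # family-wise alpha ~5% per family

    def test_injected_directions_recovered(self):
        cfg = study_effect_config(n_subjects=4000, seed=13)
        results = {r.comparison: r
                   for r in run_full_analysis(generate_cohort(cfg))}
        assert results["smoking -> median_vl"].effect < 0
        assert results["smoking -> median_vti"].effect < 0
        assert results["hypertension -> median_vti"].effect < 0
        assert results["mca_diameter_mm ~ lsa_count"].effect > 0
        assert results["mca_diameter_mm ~ median_vti"].effect < 0
        assert results["pca_diameter_mm ~ median_dm"].effect > 0

    def test_missing_column_named_in_error(self):
        table = generate_cohort(EffectConfig(seed=0)).drop(columns=["icv"])
        with pytest.raises(KeyError, match="icv"):
            run_full_analysis(table)
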