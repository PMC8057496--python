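import numpy as np
import pandas as pd
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from checkmine import (
    ClinicalTable,
    CohortSpec,
    derive_rng,
    exclude_zero_dfs,
    km_curve,
    logrank_test,
    missing_indicator_encode,
    optimal_cutpoint,
    percentile_split,
    simulate_bulk_cohort,
)
from checkmine.survival import (
    cox_univariate_then_multivariate,
    survival_at,
)


def brute_force_logrank(times, events, high):
    """Explicit risk-set tabulation, independent of the vectorized path."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    high = np.asarray(high, bool)
    O1 = E1 = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & high).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O1 - E1) ** 2 / V


class TestExcludeZeroDfs:
    def test_no_zero_identity(self, clinical_frame):
        frame = clinical_frame[clinical_frame.dfs_months > 0]
        table = ClinicalTable(data=frame.reset_index(drop=True))
        out = exclude_zero_dfs(table)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_zero_rows_removed(self, clinical_frame):
        out = exclude_zero_dfs(ClinicalTable(data=clinical_frame))
        assert len(out) == 6
        assert (out.data["dfs_months"] > 0).all()

    def test_all_zero_errors(self, clinical_frame):
        clinical_frame["dfs_months"] = 0.0
        with pytest.raises(ValueError, match="zero DFS"):
            exclude_zero_dfs(ClinicalTable(data=clinical_frame))


class TestPercentileSplit:
    def test_forty_third_of_one_to_hundred(self):
        thr, labels = percentile_split(np.arange(1.0, 101.0), 43)
        assert thr == 43.0
        assert (labels == "high").sum() == 57
        assert (labels == "low").sum() == 43

    def test_median_of_one_to_ten(self):
        thr, labels = percentile_split(np.arange(1.0, 11.0), 50)
        assert thr == 5.0
        assert set(np.arange(1.0, 11.0)[labels == "high"]) == {6, 7, 8, 9, 10}

    def test_ties_fall_into_low(self):
        values = np.array([1.0, 2.0, 2.0, 2.0, 5.0])
        thr, labels = percentile_split(values, 50)
        assert thr == 2.0
        assert labels.tolist() == ["low", "low", "low", "low", "high"]

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="split undefined"):
            percentile_split(np.full(10, 3.0), 50)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = km_curve(np.array([2.0, 5.0, 9.0]), np.zeros(3, bool))
        assert (curve["survival"] == 1.0).all()

    def test_hand_computed_product_limit(self):
        curve = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0], bool))
        assert survival_at(curve, 1) == pytest.approx(2 / 3)
        assert survival_at(curve, 2) == pytest.approx(1 / 3)
        assert survival_at(curve, 3) == pytest.approx(1 / 3)

    def test_duplicating_observations_leaves_curve_unchanged(self, rng):
        t = rng.exponential(10, 20)
        e = rng.random(20) < 0.6
        a = km_curve(t, e)
        b = km_curve(np.r_[t, t], np.r_[e, e])
        np.testing.assert_allclose(a["survival"], b["survival"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve(np.array([]), np.array([], bool))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(12, 40)
        e = rng.random(40) < 0.7
        curve = km_curve(t, e)
        km = KaplanMeierFitter().fit(t, e)
        for row in curve.itertuples():
            assert row.survival == pytest.approx(
                float(km.predict(row.time)), abs=1e-8)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 3.0, 7.0, 1.0, 3.0, 7.0])
        e = np.array([1, 0, 1, 1, 0, 1], bool)
        chi2, p = logrank_test(t, e, ["a", "a", "a", "b", "b", "b"])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_risk_set_tabulation(self):
        t = np.array([1.0, 2.0, 4.0, 3.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 0], bool)
        lab = ["A", "A", "A", "B", "B", "B"]
        chi2, p = logrank_test(t, e, lab)
        expected = brute_force_logrank(t, e, np.array(lab) == "A")
        assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_one_group_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test(np.array([1.0, 2.0]), np.array([1, 1], bool),
                         ["a", "a"])

    @settings(deadline=None, max_examples=60)
    @seed(20240901)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_instances(self, inst_seed):
        rng = np.random.default_rng(inst_seed)
        n = int(rng.integers(4, 31))
        t = np.round(rng.exponential(10, n), 1) + 0.1
        e = rng.random(n) < 0.7
        high = rng.random(n) < 0.5
        if high.all() or not high.any():
            high[0] = not high[0]
        chi2, _ = logrank_test(t, e, np.where(high, "h", "l"))
        assert chi2 == pytest.approx(brute_force_logrank(t, e, high),
                                     abs=1e-8)


def _planted_clinical(seed, **kw):
    spec = CohortSpec(n_genes=11, n_samples=320, **kw)
    expr, clin, truth = simulate_bulk_cohort(spec, derive_rng(seed, "cut"))
    clin = exclude_zero_dfs(clin)
    g = pd.Series(expr.gene(truth.planted_gene), index=expr.sample_ids)
    return g.loc[clin.sample_ids], clin


class TestOptimalCutpoint:
    def test_collapsed_scan_returns_that_percentile(self):
        g, clin = _planted_clinical(0)
        cut = optimal_cutpoint(g, clin, scan_lo=37, scan_hi=37)
        assert cut.percentile == 37
        assert len(cut.scan_trace) == 1

    def test_recovers_planted_percentile(self):
        hits = 0
        for i in range(15):
            g, clin = _planted_clinical(i, hazard_ratio=2.0)
            cut = optimal_cutpoint(g, clin)
            hits += abs(cut.percentile - 43) <= 7
        assert hits >= 12

    def test_invariant_to_monotone_transform(self):
        g, clin = _planted_clinical(3)
        a = optimal_cutpoint(g, clin)
        b = optimal_cutpoint(np.exp(g / 4.0), clin)
        assert a.percentile == b.percentile
        assert a.logrank_chi2 == pytest.approx(b.logrank_chi2)

    def test_adjusted_p_at_least_min_p(self):
        for i in range(5):
            g, clin = _planted_clinical(i, hazard_ratio=1.0)
            cut = optimal_cutpoint(g, clin, n_permutations=50,
                                   rng=derive_rng(i, "perm"))
            assert cut.permutation_adjusted_p >= cut.logrank_p

    def test_adjusted_p_deterministic(self):
        g, clin = _planted_clinical(9)
        runs = [optimal_cutpoint(g, clin, n_permutations=30,
                                 rng=derive_rng(1, "perm"))
                for _ in range(2)]
        assert (runs[0].permutation_adjusted_p
                == runs[1].permutation_adjusted_p)


class TestMissingIndicator:
    def test_no_missingness_plain_encoding(self):
        cov = pd.DataFrame({"age": [1.0, 2.0, 3.0], "sex": ["M", "F", "M"]})
        design = missing_indicator_encode(cov)
        assert list(design.columns) == ["age", "sex_M"]

    def test_numeric_mean_imputation_with_indicator(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, np.nan, 3.0]})
        design = missing_indicator_encode(cov)
        assert design["x"].tolist() == [1.0, 2.0, 2.0, 3.0]
        assert design["x_missing"].tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_indicator_sums_equal_missing_counts(self, clinical_frame):
        cov = clinical_frame[["age", "stage"]]
        design = missing_indicator_encode(cov)
        assert design["age_missing"].sum() == cov["age"].isna().sum()
        assert design["stage_missing"].sum() == cov["stage"].isna().sum()
        assert len(design) == len(cov)

    def test_fully_missing_covariate_dropped(self):
        cov = pd.DataFrame({"x": [np.nan, np.nan], "y": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="100% missing"):
            design = missing_indicator_encode(cov)
        assert list(design.columns) == ["y"]

    def test_categorical_missing_gets_reference_plus_indicator(self):
        cov = pd.DataFrame({"stage": ["II", "III", np.nan]})
        design = missing_indicator_encode(cov)
        assert design["stage_III"].tolist() == [0.0, 1.0, 0.0]
        assert design["stage_missing"].tolist() == [0.0, 0.0, 1.0]


class TestCoxStages:
    def test_planted_effect_recovered_and_selected(self):
        spec = CohortSpec(n_genes=11, n_samples=500, hazard_ratio=2.0)
        covered = 0
        for i in range(5):
            expr, clin, truth = simulate_bulk_cohort(
                spec, derive_rng(i, "cox"))
            clin = exclude_zero_dfs(clin)
            design = missing_indicator_encode(clin.covariates())
            g = pd.Series(expr.gene(truth.planted_gene),
                          index=expr.sample_ids).loc[clin.sample_ids]
            design["expr_high"] = (
                g.to_numpy() > truth.cutpoint_threshold).astype(float)
            stages = cox_univariate_then_multivariate(
                design, clin.data["dfs_months"].to_numpy(float),
                clin.data["dfs_event"].to_numpy(bool))
            assert "expr_high" in stages.selected_terms
            term = stages.multivariate.term("expr_high")
            covered += term.ci_low <= 2.0 <= term.ci_high
        assert covered >= 4

    def test_pure_noise_covariate_near_null(self):
        spec = CohortSpec(n_genes=11, n_samples=800, hazard_ratio=1.0,
                          covariate_missing_rate=0.0)
        _, clin, _ = simulate_bulk_cohort(spec, derive_rng(42, "noise"))
        clin = exclude_zero_dfs(clin)
        rng = derive_rng(42, "noisecov")
        design = pd.DataFrame({"noise": rng.standard_normal(len(clin))})
        stages = cox_univariate_then_multivariate(
            design, clin.data["dfs_months"].to_numpy(float),
            clin.data["dfs_event"].to_numpy(bool))
        hr = stages.univariate.term("noise").hazard_ratio
        assert 0.8 < hr < 1.25

    def test_empty_selection_skips_multivariate(self):
        spec = CohortSpec(n_genes=11, n_samples=300, hazard_ratio=1.0,
                          covariate_missing_rate=0.0)
        _, clin, _ = simulate_bulk_cohort(spec, derive_rng(17, "null"))
        clin = exclude_zero_dfs(clin)
        rng = derive_rng(3, "purenoise")
        design = pd.DataFrame({"noise": rng.standard_normal(len(clin))})
        stages = cox_univariate_then_multivariate(
            design, clin.data["dfs_months"].to_numpy(float),
            clin.data["dfs_event"].to_numpy(bool))
        if stages.univariate.term("noise").p >= 0.05:
            assert stages.multivariate is None
            assert stages.selected_terms == []

    def test_allowlist_carries_term_forward(self):
        spec = CohortSpec(n_genes=11, n_samples=300,
                          covariate_missing_rate=0.0)
        _, clin, _ = simulate_bulk_cohort(spec, derive_rng(8, "allow"))
        clin = exclude_zero_dfs(clin)
        design = missing_indicator_encode(clin.covariates())
        stages = cox_univariate_then_multivariate(
            design, clin.data["dfs_months"].to_numpy(float),
            clin.data["dfs_event"].to_numpy(bool), allowlist=["age"])
        assert "age" in stages.selected_terms
        assert stages.multivariate is not None
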