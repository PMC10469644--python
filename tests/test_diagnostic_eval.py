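"""ROC/AUC, DeLong, BCa bootstrap, cutoff rule, confusion identities,
avoidance, decision curves, calibration and cohort summaries."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import evfingerprint as ef
from evfingerprint.diagnostic_eval import round_half_up


class TestRocAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert ef.roc_auc(y * 1.0, y).auc == 1.0

    def test_all_tied_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        assert ef.mannwhitney_auc(np.ones(4), y) == 0.5

    def test_worked_four_patient_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        # brute force over all 4 positive-negative pairs: 3 wins / 4
        assert ef.roc_auc(scores, y).auc == pytest.approx(0.75)
        assert ef.mannwhitney_auc(scores, y) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_equals_normalized_mannwhitney_u(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        scores = rng.integers(0, 10, n).astype(float)  # heavy ties
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        curve = ef.roc_auc(scores, y)
        u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert curve.auc == pytest.approx(u / (y.sum() * (1 - y).sum()), abs=1e-12)
        assert curve.auc == pytest.approx(ef.mannwhitney_auc(scores, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ef.InputError):
            ef.roc_auc(np.arange(4.0), np.ones(4))

    def test_curve_monotonicity(self, rng):
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        curve = ef.roc_auc(scores, y)
        assert np.all(np.diff(curve.sens) >= 0)
        assert np.all(np.diff(curve.spec) <= 0)


class TestDelong:
    def test_identical_scores_give_z0_p1(self, rng):
        y = np.repeat([0, 1], 10)
        s = rng.normal(size=20)
        r = ef.delong_test(s, s, y)
        assert r.z == 0.0 and r.p == 1.0

    def test_swapping_models_negates_z(self, rng):
        y = np.repeat([0, 1], 15)
        a, b = rng.normal(size=30) + y, rng.normal(size=30)
        r1, r2 = ef.delong_test(a, b, y), ef.delong_test(b, a, y)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_variance_matches_structural_component_double_loop(self, rng):
        y = np.array([1] * 5 + [0] * 5)
        s = rng.permutation(np.arange(10.0))  # no ties
        auc, var = ef.delong_variance(s, y)
        pos, neg = s[y == 1], s[y == 0]
        psi = (pos[:, None] > neg[None, :]).astype(float)
        psi += 0.5 * (pos[:, None] == neg[None, :])
        v10, v01 = psi.mean(axis=1), psi.mean(axis=0)
        assert auc == pytest.approx(psi.mean())
        assert var == pytest.approx(v10.var(ddof=1) / 5 + v01.var(ddof=1) / 5)

    def test_p_value_within_monte_carlo_error_of_bootstrap_test(self):
        rng = np.random.default_rng(60)
        n = 60
        y = np.repeat([0, 1], 30)
        a = rng.normal(size=n) + 0.9 * y
        b = rng.normal(size=n) + 0.4 * y
        r = ef.delong_test(a, b, y)
        # stratified bootstrap of the AUC difference: z from the bootstrap sd
        diffs = np.empty(10_000)
        groups = [np.flatnonzero(y == 0), np.flatnonzero(y == 1)]
        for i in range(10_000):
            idx = np.concatenate([rng.choice(g, len(g)) for g in groups])
            diffs[i] = (ef.mannwhitney_auc(a[idx], y[idx])
                        - ef.mannwhitney_auc(b[idx], y[idx]))
        z_boot = (r.auc_a - r.auc_b) / diffs.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(z_boot))
        assert r.p == pytest.approx(p_boot, abs=0.05)

    def test_zero_variance_with_equal_aucs_returns_p_one(self):
        # both models rank every positive above every negative: the AUC
        # difference has zero variance and the curves are indistinguishable
        y = np.array([0, 0, 1, 1])
        r = ef.delong_test(np.array([0, 1, 2, 3.0]), np.array([0, 1, 3, 2.0]), y)
        assert r.auc_a == r.auc_b == 1.0
        assert r.z == 0.0 and r.p == 1.0


class TestBcaCi:
    def test_degenerate_data_zero_width_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = ef.bca_ci(np.mean, np.full(12, 3.0), n_resamples=200, seed=0)
        assert lo == hi == 3.0

    def test_symmetric_case_close_to_percentile_interval(self, rng):
        x = rng.normal(size=80)
        lo, hi = ef.bca_ci(np.mean, x, n_resamples=4000, seed=1)
        boot = np.array([rng.choice(x, 80).mean() for _ in range(4000)])
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.05)
        assert hi == pytest.approx(phi, abs=0.05)

    def test_agrees_with_scipy_bca_reference(self, rng):
        x = rng.exponential(size=40)
        lo, hi = ef.bca_ci(np.mean, x, n_resamples=6000, seed=2)
        ref = stats.bootstrap((x,), np.mean, n_resamples=6000, method="BCa",
                              random_state=3).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.06)
        assert hi == pytest.approx(ref.high, abs=0.06)

    def test_stratified_resampling_preserves_class_counts(self, rng):
        y = np.repeat([0, 1], (90, 10))
        s = rng.normal(size=100) + y

        def frac_pos_must_be_constant(scores, labels):
            if len(labels) == 100:  # bootstrap resample (jackknife drops one)
                assert labels.sum() == 10
            return ef.mannwhitney_auc(scores, labels)

        lo, hi = ef.bca_ci(frac_pos_must_be_constant, (s, y), n_resamples=200,
                           seed=4, strata=y)
        assert 0 < lo < hi <= 1


class TestCutoffAndConfusion:
    def test_separable_scores_give_perfect_operating_point(self):
        y = np.repeat([0, 1], 20)
        s = y * 10.0 + np.linspace(0, 1, 40)
        cut = ef.select_cutoff(s, y)
        cm = ef.confusion_metrics(s, y, cut)
        assert cm.sensitivity == 100.0 and cm.specificity == 100.0

    def test_matches_exhaustive_scan_oracle(self, rng):
        s = rng.normal(size=50).round(2)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        cut = ef.select_cutoff(s, y, 0.95)
        best = None  # (spec, sens, cutoff)
        for c in np.unique(s):
            pred = s >= c
            sens = (pred & (y == 1)).sum() / y.sum()
            spec = (~pred & (y == 0)).sum() / (1 - y).sum()
            if sens >= 0.95 and (best is None or (spec, sens, c) > best):
                best = (spec, sens, c)
        assert cut == pytest.approx(best[2])
        cm = ef.confusion_metrics(s, y, cut)
        assert cm.sensitivity >= 95.0

    def test_cutoff_below_all_scores_flags_everyone(self):
        y = np.repeat([0, 1], 5)
        cm = ef.confusion_metrics(np.arange(10.0), y, -1.0)
        assert cm.sensitivity == 100.0 and cm.specificity == 0.0

    def test_eight_patient_toy_against_hand_count(self):
        scores = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        # scores >= 5: outcomes (1, 1, 0, 1); below: (0, 0, 1, 0)
        cm = ef.confusion_metrics(scores, y, 5.0)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 1, 3, 1)
        assert cm.ppv == pytest.approx(75.0)
        assert cm.npv == pytest.approx(75.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_confusion_identities_hold_at_every_observed_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=40).round(1)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        for c in np.unique(s):
            cm = ef.confusion_metrics(s, y, c)
            assert cm.tp + cm.fn == y.sum()
            assert cm.tn + cm.fp == (1 - y).sum()
            assert cm.sensitivity == pytest.approx(100 * cm.tp / (cm.tp + cm.fn))
            if cm.tp + cm.fp:
                assert cm.ppv == pytest.approx(100 * cm.tp / (cm.tp + cm.fp))
            if cm.tn + cm.fn:
                assert cm.npv == pytest.approx(100 * cm.tn / (cm.tn + cm.fn))

    def test_empty_denominator_reports_nan_not_zero(self):
        y = np.repeat([0, 1], 5)
        cm = ef.confusion_metrics(np.arange(10.0), y, 100.0)  # nobody positive
        assert np.isnan(cm.ppv)
        assert cm.rounded()["ppv"] is None

    def test_confusion_cis_cover_the_point_estimate(self, rng):
        s = rng.normal(size=80) + np.repeat([0, 1.5], 40)
        y = np.repeat([0, 1], 40)
        cm = ef.confusion_metrics(s, y, 0.8, ci=True, n_resamples=400, seed=5)
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            lo, hi = cm.ci[metric]
            assert lo - 1e-9 <= getattr(cm, metric) <= hi + 1e-9


class TestAvoidance:
    def test_zero_cutoff_performs_all_biopsies(self, rng):
        s = rng.uniform(1, 99, 30)
        g = rng.integers(0, 6, 30)
        row = ef.avoidance_table(s, g, [0.0]).iloc[0]
        assert row["performed"] == 30 and row["avoided"] == 0
        assert row["performed_pct"] == 100 and row["avoided_pct"] == 0

    def test_cutoff_above_all_scores_misses_every_cancer(self, rng):
        s = rng.uniform(1, 50, 30)
        g = rng.integers(0, 6, 30)
        row = ef.avoidance_table(s, g, [99.0]).iloc[0]
        assert row["avoided"] == 30
        for k in (1, 2, 3):
            assert row[f"found_ge{k}"] == 0
            assert row[f"missed_ge{k}"] == (g >= k).sum()

    def test_ten_patient_toy_by_hand(self):
        s = np.array([2, 4, 6, 8, 12, 3, 7, 11, 9, 1.0])
        g = np.array([0, 1, 2, 3, 5, 0, 0, 2, 1, 4])
        table = ef.avoidance_table(s, g, [5.0, 10.0])
        r5 = table.iloc[0]
        assert (r5["performed"], r5["avoided"]) == (6, 4)
        assert (r5["found_ge3"], r5["missed_ge3"]) == (2, 1)  # scores 8, 12 vs 1
        r10 = table.iloc[1]
        assert (r10["performed"], r10["found_ge2"]) == (2, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_row_sums_partition_cohort_and_classes(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0, 100, 60)
        g = rng.integers(0, 6, 60)
        table = ef.avoidance_table(s, g, np.linspace(0, 100, 7))
        for _, row in table.iterrows():
            assert row["performed"] + row["avoided"] == 60
            for k in (1, 2, 3):
                assert row[f"found_ge{k}"] + row[f"missed_ge{k}"] == (g >= k).sum()


class TestDecisionCurve:
    def test_treat_none_is_identically_zero(self, rng):
        s = rng.uniform(0, 100, 40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        dc = ef.decision_curve(s, y, np.linspace(0.01, 0.9, 20))
        assert np.all(dc.net_benefit_treat_none == 0)

    def test_treat_all_tends_to_prevalence_at_small_threshold(self, rng):
        y = np.repeat([0, 1], (30, 10))
        dc = ef.decision_curve(rng.uniform(0, 100, 40), y, [1e-4])
        assert dc.net_benefit_treat_all[0] == pytest.approx(0.25, abs=1e-3)

    def test_toy_net_benefit_against_hand_formula(self):
        s = np.array([90, 80, 70, 60, 40, 30, 20, 10, 5, 1.0])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        dc = ef.decision_curve(s, y, [0.2])
        # score >= 20: TP = 4, FP = 3 -> 0.4 - 0.3 * 0.25 = 0.325
        assert dc.net_benefit_model[0] == pytest.approx(0.325)
        assert dc.net_benefit_treat_all[0] == pytest.approx(0.4 - 0.6 * 0.25)
        expected_avoided = 100 * (0.325 - 0.25) * 0.8 / 0.2
        assert dc.biopsies_avoided_per_100[0] == pytest.approx(expected_avoided)

    def test_percent_grid_accepted_and_unit_threshold_excluded(self, rng):
        y = np.repeat([0, 1], 20)
        s = rng.uniform(0, 100, 40)
        dc = ef.decision_curve(s, y, [5.0, 20.0, 100.0])
        assert np.allclose(dc.thresholds, [0.05, 0.20])

    def test_perfect_model_dominates_noisy_clinical_model(self, rng):
        y = np.repeat([0, 1], 50)
        perfect = y * 100.0
        noisy = np.clip(50 + 20 * (y - 0.5) + rng.normal(0, 25, 100), 0, 100)
        grid = np.linspace(0.05, 0.9, 18)
        nb_perfect = ef.decision_curve(perfect, y, grid).net_benefit_model
        nb_noisy = ef.decision_curve(noisy, y, grid).net_benefit_model
        assert np.all(nb_perfect >= nb_noisy - 1e-12)


class TestCalibration:
    def test_calibrated_by_construction_within_3_points(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 100, 10_000)
        y = (rng.random(10_000) < scores / 100.0).astype(int)
        curve = ef.calibration_curve(scores, y, n_groups=10)
        assert len(curve) == 10
        assert np.max(np.abs(curve["observed_pct"] - curve["mean_predicted"])) < 3.0

    def test_constant_score_merges_to_single_group(self):
        rng = np.random.default_rng(8)
        y = (rng.random(1000) < 0.3).astype(int)
        with pytest.warns(UserWarning, match="groups"):
            curve = ef.calibration_curve(np.full(1000, 30.0), y, n_groups=10)
        assert len(curve) == 1
        assert curve["mean_predicted"].iloc[0] == 30.0
        assert curve["observed_pct"].iloc[0] == pytest.approx(100 * y.mean())

    def test_monotone_transform_preserves_groups_and_observed_rates(self, rng):
        scores = rng.uniform(1, 99, 2000)
        y = rng.integers(0, 2, 2000)
        a = ef.calibration_curve(scores, y)
        b = ef.calibration_curve(np.sqrt(scores) * 10, y)
        assert np.allclose(a["observed_pct"], b["observed_pct"])
        assert np.array_equal(a["n"], b["n"])


class TestCohortSummary:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(9)
        half = pd.DataFrame({
            "age": rng.normal(63, 5, 40), "psa": rng.lognormal(1.8, 0.4, 40),
            "bmi": rng.normal(27, 3, 40),
            **{c: rng.integers(0, 2, 40).astype(float)
               for c in ("race_black", "prior_negative_biopsy", "family_history",
                         "diabetes", "dre_abnormal")}})
        records = pd.concat([half, half], ignore_index=True)
        mask = np.repeat([False, True], 40)
        out = ef.cohort_summary(records, mask)
        assert np.allclose(out["p_value"], 1.0)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # groups of 10 with 8/2 and 2/8 positives
        records = pd.DataFrame({"dre_abnormal": [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8})
        mask = np.repeat([False, True], 10)
        out = ef.cohort_summary(records, mask, continuous=(), binary=("dre_abnormal",))
        # two-sided Fisher: sum of hypergeometric probabilities <= P(observed)
        rv = stats.hypergeom(20, 10, 10)  # N, successes, draws from group 0
        p_obs = rv.pmf(8)
        expected = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert out["p_value"].iloc[0] == pytest.approx(expected)

    def test_table_layout_on_synthetic_cohort(self, small_cohort):
        _, _, records, _ = small_cohort
        y = records["grade_group"].to_numpy() >= 3
        out = ef.cohort_summary(records, y)
        assert set(out.loc[out["test"] == "mannwhitney", "covariate"]) == {"age", "psa", "bmi"}
        assert {"g0_median", "g1_median", "p_value"} <= set(out.columns)
        fisher = out[out["test"] == "fisher"]
        assert len(fisher) == 5 and fisher["p_value"].notna().all()

    def test_empty_group_rejected(self):
        records = pd.DataFrame({"age": [60.0, 61.0]})
        with pytest.raises(ef.InputError):
            ef.cohort_summary(records, np.array([True, True]))


def test_round_half_up_matches_display_convention():
    assert round_half_up(34.7) == 35
    assert round_half_up(5.48) == 5
    assert round_half_up(17.5) == 18
    assert round_half_up(2.5) == 3
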