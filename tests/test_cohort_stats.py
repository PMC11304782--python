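"""Cohort aggregation, outlier exclusion and the paired inferential chain."""

import itertools

import numpy as np
import pytest
from scipy import stats

from copsway import (
    ValidationError,
    assign_orders,
    ci_from_summary,
    detect_outliers,
    effect_of_stimuli,
    normality_diagnostics,
    paired_t_test,
    simulate_cohort,
    summarize_cohort,
)


class TestDetectOutliers:
    def test_single_large_lateral_value_excluded(self):
        """A cohort whose 29 retained values stay at or below the box-plot
        whisker while one participant far exceeds the upper fence."""
        rng = np.random.default_rng(1)
        values = {f"P{i:02d}": v for i, v in enumerate(rng.uniform(5.5, 7.62, 29))}
        values["P30"] = 9.42
        res = detect_outliers(values)
        assert res.excluded == {"P30"}
        assert res.upper_fence < 9.42
        assert max(v for k, v in values.items() if k != "P30") <= res.upper_fence

    def test_all_equal_values_give_empty_set(self):
        res = detect_outliers({f"p{i}": 4.2 for i in range(8)})
        assert res.excluded == frozenset()

    def test_value_exactly_at_fence_is_retained(self):
        # seven identical values make IQR = 0, so both fences sit at the
        # common value; the eighth participant sits exactly on the fence
        values = {f"p{i}": 1.0 for i in range(7)}
        values["edge"] = 1.0
        assert detect_outliers(values).excluded == frozenset()
        values["edge"] = 1.1  # strictly above -> excluded
        assert detect_outliers(values).excluded == {"edge"}

    def test_lower_fence_applies_too(self):
        values = {f"p{i}": v for i, v in enumerate([10.0] * 9)}
        values["low"] = 2.0
        assert detect_outliers(values).excluded == {"low"}

    def test_rerun_with_frozen_fences_is_noop(self):
        rng = np.random.default_rng(2)
        values = {f"p{i}": v for i, v in enumerate(rng.uniform(0, 3, 20))}
        values["out"] = 50.0
        first = detect_outliers(values)
        kept = {k: v for k, v in values.items() if k not in first.excluded}
        survivors = {
            k for k, v in kept.items()
            if first.lower_fence <= v <= first.upper_fence
        }
        assert survivors == set(kept)

    @pytest.mark.parametrize("values", [{}, {"a": 1.0, "b": 2.0}])
    def test_too_few_participants_rejected(self, values):
        with pytest.raises(ValidationError):
            detect_outliers(values)


class TestEffectOfStimuli:
    def test_eccentricity_ratio_matches_reported_rounding(self):
        # background 0.87 vs standard stimuli 0.88: ratio rounds to 1.01
        assert effect_of_stimuli("eccentricity", 0.87, 0.88) == pytest.approx(
            0.88 / 0.87
        )
        assert round(effect_of_stimuli("eccentricity", 0.87, 0.88), 2) == 1.01

    def test_declination_difference(self):
        assert effect_of_stimuli("declination", -0.92, 6.32) == pytest.approx(7.24)

    @pytest.mark.parametrize("metric", ["eccentricity", "long_diameter"])
    def test_identical_values_ratio_one(self, metric):
        assert effect_of_stimuli(metric, 3.3, 3.3) == 1.0

    @pytest.mark.parametrize("metric", ["declination", "lateral_component"])
    def test_identical_values_difference_zero(self, metric):
        assert effect_of_stimuli(metric, 3.3, 3.3) == 0.0

    def test_zero_denominator_ratio_rejected(self):
        with pytest.raises(ValidationError):
            effect_of_stimuli("long_diameter", 0.0, 5.0)

    @pytest.mark.parametrize(
        "alias, canonical",
        [("eps", "eccentricity"), ("delta", "long_diameter"),
         ("theta", "declination"), ("psi", "lateral_component")],
    )
    def test_greek_aliases(self, alias, canonical):
        assert effect_of_stimuli(alias, 2.0, 3.0) == effect_of_stimuli(
            canonical, 2.0, 3.0
        )

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError):
            effect_of_stimuli("sway_area", 1.0, 2.0)


class TestPairedTTest:
    def test_identical_samples_degenerate(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_two_sided == 1.0
        assert res.ci95 == (0.0, 0.0)
        assert res.degenerate

    def test_symmetric_differences(self):
        b = np.array([5.0, 5.0, 5.0])
        a = b + np.array([-1.0, 0.0, 1.0])
        res = paired_t_test(a, b)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        half_width = stats.t.ppf(0.975, 2) / np.sqrt(3)
        assert res.ci95[0] == pytest.approx(-half_width, rel=1e-9)
        assert res.ci95[1] == pytest.approx(half_width, rel=1e-9)

    def test_agrees_with_scipy(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        res = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == 24

    def test_swap_reflects_statistics(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        r1 = paired_t_test(a, b)
        r2 = paired_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t, rel=1e-12)
        assert r1.mean_difference == pytest.approx(-r2.mean_difference, rel=1e-12)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, rel=1e-12)
        assert r1.ci95[0] == pytest.approx(-r2.ci95[1], rel=1e-9)
        assert r1.ci95[1] == pytest.approx(-r2.ci95[0], rel=1e-9)

    def test_expected_t_at_reported_effect_size(self):
        """With the mean difference of -7.241363 at t = -2.4917 and n = 29,
        the implied sd of differences is |md| sqrt(n)/|t| = 15.65; simulating
        at those moments reproduces the t statistic in expectation."""
        sd_d = 7.241363 * np.sqrt(29) / 2.4917
        assert sd_d == pytest.approx(15.65, abs=0.01)
        rng = np.random.default_rng(99)
        tvals = []
        for _ in range(3000):
            d = rng.normal(-7.241363, sd_d, size=29)
            tvals.append(paired_t_test(d, np.zeros(29)).t)
        # E[t] exceeds the plug-in value slightly because E[1/sd] > 1/E[sd]
        assert np.mean(tvals) == pytest.approx(-2.4917, abs=0.15)

    def test_constant_nonzero_difference_flagged_undefined(self):
        res = paired_t_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert res.degenerate
        assert np.isinf(res.t) and res.t > 0
        assert np.isnan(res.p_two_sided)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0])


class TestCiFromSummary:
    def test_reported_summary_reproduces_interval(self):
        lo, hi = ci_from_summary(-7.241363, -2.4917, 28)
        assert round(lo, 2) == -13.19
        assert round(hi, 2) == -1.29

    def test_consistency_with_paired_test(self, rng):
        a = rng.normal(1.0, 2.0, size=20)
        b = rng.normal(size=20)
        res = paired_t_test(a, b)
        lo, hi = ci_from_summary(res.mean_difference, res.t, res.df)
        assert lo == pytest.approx(res.ci95[0], abs=1e-9)
        assert hi == pytest.approx(res.ci95[1], abs=1e-9)

    def test_large_df_limit_is_normal_interval(self):
        lo, hi = ci_from_summary(1.0, 2.0, 10**7)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(1.0 - z * 0.5, abs=1e-4)
        assert hi == pytest.approx(1.0 + z * 0.5, abs=1e-4)

    def test_zero_t_rejected(self):
        with pytest.raises(ValidationError):
            ci_from_summary(1.0, 0.0, 10)


class TestNormalityDiagnostics:
    def test_near_normal_quantiles_have_tiny_ks_distance(self):
        n = 100
        d = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        ks_D, ks_p, W, sw_p = normality_diagnostics(d)
        # brute-force oracle: sup over both corners of every CDF step of the
        # standardized sample
        z = np.sort((d - d.mean()) / d.std(ddof=1))
        cdf = stats.norm.cdf(z)
        steps_hi = np.abs(np.arange(1, n + 1) / n - cdf)
        steps_lo = np.abs(np.arange(0, n) / n - cdf)
        brute_D = max(steps_hi.max(), steps_lo.max())
        assert ks_D == pytest.approx(brute_D, abs=1e-12)
        assert ks_D <= 0.01
        assert W <= 1.0

    def test_gross_outlier_rejected_by_shapiro(self, rng):
        d = np.concatenate([rng.normal(size=28), [10.0]])
        _, _, _, sw_p = normality_diagnostics(d)
        assert sw_p < 0.01

    def test_w_bounded_by_one(self, rng):
        for _ in range(10):
            d = rng.normal(size=int(rng.integers(5, 50)))
            _, _, W, _ = normality_diagnostics(d)
            assert W <= 1.0

    def test_constant_differences_rejected(self):
        with pytest.raises(ValidationError):
            normality_diagnostics([1.0, 1.0, 1.0, 1.0])


class TestAssignOrders:
    def test_thirty_participants_balanced_five_per_order(self):
        orders = assign_orders([f"P{i}" for i in range(30)])
        counts = {}
        for o in orders.values():
            counts[o] = counts.get(o, 0) + 1
        assert len(counts) == 6
        assert set(counts.values()) == {5}
        assert set(counts) == set(itertools.permutations(("bone", "closed", "ears_free")))

    def test_six_participants_each_order_once(self):
        orders = assign_orders([f"P{i}" for i in range(6)])
        assert len(set(orders.values())) == 6

    def test_remainder_round_robin_with_warning(self):
        with pytest.warns(UserWarning):
            orders = assign_orders([f"P{i}" for i in range(7)])
        counts = {}
        for o in orders.values():
            counts[o] = counts.get(o, 0) + 1
        assert sorted(counts.values()) == [1, 1, 1, 1, 1, 2]

    def test_deterministic_given_seed(self):
        ids = [f"P{i}" for i in range(12)]
        assert assign_orders(ids, seed=5) == assign_orders(ids, seed=5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            assign_orders([])


@pytest.fixture(scope="module")
def stimulated():
    cohort = simulate_cohort(n_participants=12, seed=21, include_outlier=True)
    return summarize_cohort(cohort.trajectories), cohort


class TestSummarizeCohort:

    def test_injected_outlier_excluded(self, stimulated):
        summary, cohort = stimulated
        assert cohort.outlier_id in summary.outliers.excluded
        assert cohort.outlier_id not in summary.retained

    def test_table_shape(self, stimulated):
        summary, _ = stimulated
        cells = set(
            map(tuple, summary.condition_means[["condition", "trial"]].to_numpy())
        )
        assert ("silent", 1) in cells and ("ears_free", 2) in cells
        assert len(cells) == 8  # silent + array + 3 headphones x 2 trials
        assert set(summary.effects["contrast"]) == {
            "silent_vs_array_only",
            "bone_trial1_vs_trial2",
            "closed_trial1_vs_trial2",
            "ears_free_trial1_vs_trial2",
        }

    def test_ears_free_declination_contrast_significant(self, stimulated):
        summary, _ = stimulated
        res = summary.tests[("ears_free", 1)]
        assert res.p_two_sided < 0.05
        # array-only minus ears-free: the stimulated condition tilts left
        assert res.mean_difference < 0

    def test_habituation_attenuates_second_trial(self, stimulated):
        summary, _ = stimulated
        cm = summary.condition_means.set_index(["condition", "trial"])
        assert (
            cm.loc[("ears_free", 2), "declination"]
            < cm.loc[("ears_free", 1), "declination"]
        )

    def test_null_cohort_shows_no_tilt(self):
        from copsway import SimulationConfig

        zero = {c: 0.0 for c in ("silent", "array_only", "bone", "closed", "ears_free")}
        cohort = simulate_cohort(
            SimulationConfig(gains_mm=zero), n_participants=18, seed=8
        )
        summary = summarize_cohort(cohort.trajectories)
        assert summary.condition_means["declination"].abs().max() < 8.0
        assert summary.condition_means["lateral_component"].abs().max() < 1.5

    def test_single_participant_refuses_tests(self, fast_config):
        with pytest.warns(UserWarning):
            cohort = simulate_cohort(fast_config, n_participants=1, seed=0)
        summary = summarize_cohort(cohort.trajectories)
        assert summary.tests == {}
        assert any("refused" in line for line in summary.exclusion_log)
        assert len(summary.condition_means) > 0

    def test_missing_silent_record_logged(self, fast_config):
        cohort = simulate_cohort(fast_config, n_participants=8, seed=3)
        trimmed = [
            tr for tr in cohort.trajectories
            if not (tr.participant_id == "P01" and tr.condition == "silent")
        ]
        summary = summarize_cohort(trimmed)
        assert "P01" not in summary.retained
        assert any("P01" in line and "silent" in line for line in summary.exclusion_log)

    def test_holm_adjustment_not_below_raw(self):
        cohort = simulate_cohort(n_participants=8, seed=14)
        summary = summarize_cohort(cohort.trajectories, holm=True)
        for key, p_adj in summary.holm_adjusted_p.items():
            assert p_adj >= summary.tests[key].p_two_sided - 1e-12
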