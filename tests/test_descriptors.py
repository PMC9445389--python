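import numpy as np
import pytest

from locotrack.descriptors import (
    ActivityClassSeries,
    TrendFit,
    activity_rmse,
    activity_skewness,
    bird_entropy,
    classes_from_counts,
    default_entropy_r,
    fit_individual_trend,
    flag_outliers,
    lag1_autocorrelation,
    mean_distance,
    minute_activity_classes,
    sample_entropy,
)

from _oracles import brute_sample_entropy
from conftest import make_stream

NAN = float("nan")


class TestMeanDistance:
    @pytest.mark.parametrize("values,expected", [
        ((10, 20, 30), 20.0),
        ((10, NAN, 30), 20.0),   # missing days excluded
    ])
    def test_mean_over_observed_days(self, values, expected):
        assert mean_distance(values) == expected

    def test_all_missing_is_missing(self):
        assert np.isnan(mean_distance([NAN, NAN]))


class TestSkewness:
    def test_symmetric_series_is_zero(self):
        assert activity_skewness([1, 2, 3]) == pytest.approx(0.0)

    def test_moment_ratio_matches_reference_package(self):
        # b1 = m3 / s^3 with s the (n-1)-denominator SD: m3 = 6, s = 2
        # -> 0.75, the value R's e1071::skewness returns for this series
        assert activity_skewness([1, 1, 1, 5]) == pytest.approx(0.75, abs=1e-12)

    def test_constant_series_is_missing(self):
        assert np.isnan(activity_skewness([2, 2, 2, 2]))

    def test_too_few_days_is_missing(self):
        assert np.isnan(activity_skewness([1, 2]))

    def test_missing_day_does_not_change_value(self):
        assert activity_skewness([1, 1, NAN, 1, 5]) == activity_skewness([1, 1, 1, 5])


class TestTrendFit:
    def test_collinear_points_have_zero_residuals(self):
        ages = np.arange(1, 16)
        fit = fit_individual_trend(ages, 5 - 0.2 * ages)
        assert np.allclose(fit.residuals, 0, atol=1e-12)
        assert fit.slope == pytest.approx(-0.2)

    def test_three_point_closed_form(self):
        fit = fit_individual_trend([1, 2, 3], [1, 3, 2])
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1.0)
        assert np.allclose(fit.residuals, [-0.5, 1.0, -0.5])

    def test_shift_equivariance(self):
        base = fit_individual_trend([1, 2, 3, 5], [4.0, 2.5, 3.5, 1.0])
        shifted = fit_individual_trend([1, 2, 3, 5], [7.0, 5.5, 6.5, 4.0])
        assert shifted.intercept == pytest.approx(base.intercept + 3.0)
        assert np.allclose(shifted.residuals, base.residuals)

    def test_missing_days_absent_from_fit(self):
        fit = fit_individual_trend([1, 2, 3, 4], [1, NAN, 3, 2])
        assert fit.n == 3 and fit.ages.tolist() == [1, 3, 4]

    def test_too_few_days_gives_no_fit(self):
        assert fit_individual_trend([1, 2], [1.0, 2.0]) is None
        assert np.isnan(activity_rmse(None))
        assert np.isnan(lag1_autocorrelation(None))


class TestRmse:
    def _fit(self, resid, ages=None):
        resid = np.asarray(resid, dtype=float)
        ages = np.arange(1, resid.size + 1) if ages is None else np.asarray(ages)
        return TrendFit("b", 0.0, 0.0, ages, resid, resid.size)

    def test_zero_residuals(self):
        assert activity_rmse(self._fit([0, 0, 0])) == 0.0

    def test_divisor_is_n(self):
        # sqrt(1.5 / 3), not sqrt(1.5 / 1)
        assert activity_rmse(self._fit([-0.5, 1.0, -0.5])) == pytest.approx(np.sqrt(0.5))

    def test_unit_residuals(self):
        assert activity_rmse(self._fit([1, -1, 1, -1])) == 1.0


class TestAutocorrelation:
    def _fit(self, resid, ages=None):
        resid = np.asarray(resid, dtype=float)
        ages = np.arange(1, resid.size + 1) if ages is None else np.asarray(ages)
        return TrendFit("b", 0.0, 0.0, ages, resid, resid.size)

    def test_perfect_alternation(self):
        assert lag1_autocorrelation(self._fit([1, -1, 1, -1, 1])) == pytest.approx(-1.0)

    def test_white_noise_is_near_zero(self):
        rng = np.random.default_rng(5)
        ac = lag1_autocorrelation(self._fit(rng.normal(size=10_000)))
        assert abs(ac) < 0.05

    def test_requires_three_consecutive_age_pairs(self):
        # ages (1,2,4,5): only pairs (1,2) and (4,5) exist
        fit = self._fit([1.0, -1.0, 1.0, -1.0], ages=[1, 2, 4, 5])
        assert np.isnan(lag1_autocorrelation(fit))

    def test_pairs_respect_age_adjacency_not_observation_order(self):
        # ages (1,2,3,7,8,9): pairs (1,2),(2,3),(7,8),(8,9) - the (3,7)
        # observation pair is not consecutive in age and must not be used
        fit = self._fit([1.0, -1.0, 1.0, 1.0, -1.0, 1.0], ages=[1, 2, 3, 7, 8, 9])
        assert lag1_autocorrelation(fit) == pytest.approx(-1.0)

    def test_zero_variance_is_missing(self):
        assert np.isnan(lag1_autocorrelation(self._fit([1.0, 1.0, 1.0, 1.0, 1.0])))


class TestMinuteClasses:
    def test_class_boundaries(self):
        assert classes_from_counts(np.array([0, 2, 3, 4, 5, 7, 8, 15])).tolist() == \
            [1, 1, 2, 2, 3, 3, 4, 4]

    def test_no_switches_gives_all_class_one(self):
        s = make_stream(np.arange(25_200, 82_800, 60), np.full(960, 9))
        cs = minute_activity_classes(s)
        assert cs.counts.sum() == 0 and (cs.classes == 1).all() and cs.complete

    def test_switch_minutes_counted_once_per_minute(self):
        # six minutes with a switch in the first 15-min bin -> class 3;
        # repeated switches within one minute count that minute once
        times, ants = [25_200], [1]
        for m in range(6):
            times += [25_200 + 60 * m + 10, 25_200 + 60 * m + 20]
            ants += [2, 1]
        s = make_stream(times, ants)
        cs = minute_activity_classes(s)
        assert cs.counts[0] == 6 and cs.classes[0] == 3
        assert cs.counts[1:].sum() == 0

    def test_incomplete_day_flagged(self):
        s = make_stream([30_000], [1], effective_seconds=54_000)
        assert not minute_activity_classes(s).complete

    def test_switch_across_excluded_segment_not_counted(self):
        s = make_stream([30_000, 40_000], [1, 2], segments=[0, 1])
        assert minute_activity_classes(s).counts.sum() == 0


class TestSampleEntropy:
    def test_alternating_series_closed_form(self):
        # 62 length-2 templates: 31 (1,2) + 31 (2,1) -> B = 2*C(31,2) = 930
        # 61 length-3 templates: 31 (1,2,1) + 30 (2,1,2) -> A = 900
        x = np.tile([1, 2], 32)
        assert sample_entropy(x, m=2, r=0.1) == pytest.approx(-np.log(900 / 930), abs=1e-15)

    def test_constant_series_near_zero(self):
        # all templates match; the value is the small positive finite-size
        # offset -ln(C(61,2)/C(62,2)) of the template-count convention
        x = np.full(64, 3.0)
        assert sample_entropy(x, m=2, r=0.2) == pytest.approx(-np.log(60 / 62))
        assert sample_entropy(x, m=2, r=0.2) < 0.05

    def test_matches_brute_force_template_counting(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.integers(1, 5, size=64)
            r = default_entropy_r(x)
            expected = brute_sample_entropy(x, 2, r)
            got = sample_entropy(x, m=2, r=r)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_random_exceeds_periodic(self):
        rng = np.random.default_rng(7)
        alt = sample_entropy(np.tile([1, 2], 32), m=2, r=0.5)
        rand_mean = np.mean([
            sample_entropy(rng.integers(1, 5, size=64), m=2, r=0.5) for _ in range(200)])
        assert rand_mean > alt

    def test_close_to_reference_r_implementation(self):
        # value frozen from R pracma::sample_entropy on this series; the
        # conventions differ only in one boundary template
        y = np.array([2, 3, 3, 4, 3, 2, 3, 2, 2, 4, 4, 3, 4, 4, 2, 3, 4, 3, 2, 4, 3, 4,
                      4, 2, 3, 3, 2, 4, 2, 3, 1, 4, 3, 2, 2, 3, 2, 4, 2, 4, 3, 4, 4, 1,
                      3, 2, 4, 1, 3, 1, 1, 4, 1, 1, 2, 4, 1, 3, 1, 3, 2, 4, 4, 1])
        assert sample_entropy(y, m=2, r=default_entropy_r(y)) == pytest.approx(1.264279, abs=0.05)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            sample_entropy([1, 2, 3], m=2)


class TestBirdEntropy:
    def _day(self, classes, complete=True):
        classes = np.asarray(classes)
        return ActivityClassSeries("b", 1, classes, classes, complete)

    def test_mean_over_complete_days(self):
        rng = np.random.default_rng(3)
        d1, d2 = rng.integers(1, 5, size=(2, 64))
        expected = np.mean([sample_entropy(d, 2, default_entropy_r(d)) for d in (d1, d2)])
        assert bird_entropy([self._day(d1), self._day(d2)]) == pytest.approx(expected)

    def test_incomplete_days_excluded(self):
        rng = np.random.default_rng(4)
        d1, d2, d3 = rng.integers(1, 5, size=(3, 64))
        full = bird_entropy([self._day(d1), self._day(d2)])
        with_incomplete = bird_entropy([self._day(d1), self._day(d2), self._day(d3, False)])
        assert with_incomplete == full

    def test_no_complete_days_is_missing(self):
        assert np.isnan(bird_entropy([self._day(np.ones(64), complete=False)]))


class TestOutlierFlagging:
    def test_all_equal_no_flags(self):
        assert not flag_outliers([5.0] * 10, ["r1"] * 10).any()

    def test_large_group_flags_extreme_value(self):
        # 100 at 10 plus one at 1000: mean ~ 19.8, SD ~ 98.5, 4*SD < 980
        v = [10.0] * 100 + [1000.0]
        mask = flag_outliers(v, ["r1"] * 101)
        assert mask.tolist() == [False] * 100 + [True]

    def test_small_group_extreme_value_masks_itself(self):
        # 9 at 10 plus one at 1000: the outlier inflates the SD it is
        # tested against (4*SD ~ 1252 > 891), so nothing is flagged
        v = [10.0] * 9 + [1000.0]
        assert not flag_outliers(v, ["r1"] * 10).any()

    def test_groups_are_independent(self):
        v = [10.0] * 100 + [1000.0] + [1000.0] * 5
        groups = ["r1"] * 101 + ["r2"] * 5
        mask = flag_outliers(v, groups)
        assert mask[100] and not mask[101:].any()

    def test_missing_values_ignored(self):
        v = [10.0] * 100 + [np.nan, 1000.0]
        mask = flag_outliers(v, ["r1"] * 102)
        assert not mask[100] and mask[101]
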