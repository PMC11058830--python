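"""Trend/variability statistics against brute-force and library oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from hydroscale.core import (CalendarWindow, DataQualityError, InputFormatError,
                             MonthlyTimeSeries, RasterStack, YearMonth)
from hydroscale.synthetic import gen_trend_raster, gen_water_stack
from hydroscale.trends import (classify_cv, classify_trend,
                               coefficient_of_variation, mann_kendall,
                               pixelwise, theil_sen, vegetation_mask,
                               water_frequency)


def _brute_sen(t, v):
    return float(np.median([(v[j] - v[i]) / (t[j] - t[i])
                            for i, j in itertools.combinations(range(len(v)), 2)]))


def _brute_mk_s(v):
    return sum(np.sign(v[j] - v[i])
               for i, j in itertools.combinations(range(len(v)), 2))


class TestTheilSen:
    def test_exact_line(self):
        s, sy = theil_sen(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s == 1.0 and sy == 12.0

    def test_constant(self):
        s, _ = theil_sen(np.full(10, 2.5))
        assert s == 0.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(3, 31)
            v = rng.normal(size=n)
            t = np.arange(n, dtype=float)
            s, _ = theil_sen(v)
            assert s == _brute_sen(t, v)

    def test_matches_scipy(self, rng):
        v = rng.normal(size=50).cumsum()
        s, _ = theil_sen(v)
        assert s == pytest.approx(sstats.theilslopes(v).slope, rel=1e-12)

    def test_missing_entries_keep_time_axis(self):
        vals = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
        ts = MonthlyTimeSeries(start=YearMonth(2001, 1), values=vals)
        s, _ = theil_sen(ts)
        assert s == 1.0

    def test_insufficient_data(self):
        with pytest.raises(DataQualityError):
            theil_sen(np.array([1.0, 2.0]))


class TestMannKendall:
    def test_strictly_increasing_small(self):
        r = mann_kendall(np.array([1.0, 2.0, 3.0, 4.0]))
        assert r.mk_s == 6

    def test_tie_correction_by_hand(self):
        # [1,1,2,2]: 4 concordant pairs; two tie groups of size 2
        r = mann_kendall(np.array([1.0, 1.0, 2.0, 2.0]))
        assert r.mk_s == 4
        assert r.mk_var_s == pytest.approx((4 * 3 * 13 - 2 * (2 * 1 * 9)) / 18)

    def test_reversal_antisymmetry(self, rng):
        v = rng.normal(size=40).cumsum()
        a = mann_kendall(v)
        b = mann_kendall(v[::-1].copy())
        assert a.mk_s == -b.mk_s
        assert a.mk_p == pytest.approx(b.mk_p)

    def test_all_tied(self):
        r = mann_kendall(np.full(12, 7.0))
        assert r.mk_s == 0 and r.mk_p == 1.0

    def test_matches_pair_enumeration_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 60))
            # integer draws force ties
            v = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(v) == 0:
                continue
            r = mann_kendall(v)
            assert r.mk_s == _brute_mk_s(v)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(77)
        rejections = 0
        sims = 600
        for _ in range(sims):
            if mann_kendall(rng.normal(size=60)).mk_p < 0.05:
                rejections += 1
        assert rejections / sims == pytest.approx(0.05, abs=0.025)

    def test_sen_estimator_recovers_known_slope(self):
        rng = np.random.default_rng(5)
        b, sigma, n = 0.05, 1.0, 240
        slopes = []
        for _ in range(200):
            y = 1.0 + b * np.arange(n) + rng.normal(0, sigma, n)
            slopes.append(theil_sen(y)[0])
        assert np.mean(slopes) == pytest.approx(b, rel=0.05)


class TestClassification:
    @pytest.mark.parametrize("slope,label", [
        (0.002, "improved"), (0.0, "stable"), (-0.001, "degraded"),
        (0.0005, "improved"), (-0.0005, "stable"),
        (0.00049999, "stable"), (-0.00050001, "degraded"),
    ])
    def test_trend_boundaries(self, slope, label):
        assert classify_trend(slope) == label

    @pytest.mark.parametrize("cv,label", [
        (0.0, "Low volatility"), (0.22, "High volatility"),
        (0.07, "Relatively low volatility"),
        (0.05, "Relatively low volatility"), (0.0499999, "Low volatility"),
        (0.10, "Medium volatility"), (0.15, "Relative-high volatility"),
        (0.20, "High volatility"), (0.1999999, "Relative-high volatility"),
    ])
    def test_cv_boundaries(self, cv, label):
        assert classify_cv(cv) == label

    def test_cv_constant_series(self):
        r = coefficient_of_variation(np.full(5, 3.0))
        assert r.cv == 0.0 and r.class_label == "Low volatility"

    def test_cv_uses_sample_sd(self):
        v = np.array([1.0, 2.0, 3.0])
        r = coefficient_of_variation(v)
        assert r.cv == pytest.approx(1.0 / 2.0)

    def test_cv_nonpositive_mean_rejected(self):
        with pytest.raises(DataQualityError):
            coefficient_of_variation(np.array([-1.0, 0.0, -2.0]))


class TestVegetationMask:
    def _stack(self, fill):
        return RasterStack(data=np.full((24, 3, 3), fill), start=YearMonth(2001, 1))

    def test_dense_canopy_all_true(self):
        assert vegetation_mask(self._stack(0.5)).all()

    def test_bare_ground_all_false(self):
        assert not vegetation_mask(self._stack(0.05)).any()

    def test_threshold_inclusive(self):
        assert vegetation_mask(self._stack(0.1)).all()

    def test_every_year_stricter_than_mean(self):
        data = np.full((24, 1, 1), 0.3)
        data[:12] = 0.05  # first growing season below threshold
        stack = RasterStack(data=data, start=YearMonth(2001, 1))
        assert not vegetation_mask(stack, rule="every_year").any()
        assert vegetation_mask(stack, rule="mean_of_years").all()


class TestWaterFrequency:
    def test_always_wet_is_100(self):
        stack = RasterStack(data=np.ones((12, 2, 2)), start=YearMonth(2001, 1))
        fm = water_frequency(stack)
        assert (fm.frequency == 100.0).all() and fm.permanent.all()

    def test_half_wet_is_50(self):
        data = np.zeros((8, 1, 1))
        data[:4] = 1.0
        fm = water_frequency(RasterStack(data=data, start=YearMonth(2001, 1)))
        assert fm.frequency[0, 0] == 50.0

    def test_at_risk_fraction_from_generator_truth(self):
        stack, truth = gen_water_stack((20, 20), 60, 0.8, 0.5, seed=3)
        fm = water_frequency(stack)
        assert fm.at_risk_fraction == pytest.approx(truth["at_risk_fraction"])
        assert fm.at_risk_fraction == pytest.approx(0.2)

    def test_non_binary_rejected(self):
        stack = RasterStack(data=np.full((6, 2, 2), 0.5), start=YearMonth(2001, 1))
        with pytest.raises(InputFormatError):
            water_frequency(stack)

    def test_window_restriction(self):
        # wet only in March-October -> 100% within the growing season
        data = np.zeros((24, 1, 1))
        months = (np.arange(24) % 12) + 1
        data[(months >= 3) & (months <= 10)] = 1.0
        stack = RasterStack(data=data, start=YearMonth(2001, 1))
        fm = water_frequency(stack, CalendarWindow(3, 10))
        assert fm.frequency[0, 0] == 100.0


class TestPixelwise:
    def test_noiseless_slope_field_recovered(self):
        slope = np.linspace(0.001, 0.005, 9).reshape(3, 3)
        stack = gen_trend_raster((3, 3), slope, np.zeros((3, 3)), 60, seed=0)
        out = pixelwise("theil_sen", stack)
        np.testing.assert_allclose(out["maps"]["sen_slope"], slope, atol=1e-12)

    def test_single_pixel_equals_scalar(self, rng):
        series = rng.normal(size=60).cumsum() + 10
        stack = RasterStack(data=series[:, None, None], start=YearMonth(2001, 1))
        out = pixelwise("mann_kendall", stack)
        scalar = mann_kendall(series)
        assert out["maps"]["mk_z"][0, 0] == pytest.approx(scalar.mk_z)
        assert out["maps"]["sen_slope"][0, 0] == pytest.approx(scalar.sen_slope)

    def test_class_percentages_sum_to_100(self, rng):
        data = rng.normal(size=(60, 5, 5)).cumsum(axis=0) + 50
        out = pixelwise("theil_sen", RasterStack(data=data, start=YearMonth(2001, 1)))
        assert sum(out["classes"].percentages.values()) == pytest.approx(100.0)

    def test_mostly_missing_pixel_excluded(self, rng):
        data = rng.normal(size=(60, 2, 2)) + 10
        nodata = np.zeros_like(data, dtype=bool)
        nodata[:30, 0, 0] = True  # 50% missing
        stack = RasterStack(data=data, start=YearMonth(2001, 1), nodata=nodata)
        out = pixelwise("theil_sen", stack)
        assert not out["valid"][0, 0]
        assert out["valid"][1, 1]
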