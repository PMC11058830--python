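"""Generator contracts: determinism, analytic structure, ground-truth exactness."""

import numpy as np
import pytest

from hydroscale.core import YearMonth  # noqa: F401
from hydroscale.eemd import find_extrema
from hydroscale.synthetic import (ConfigError, CouplingSpec, HarmonicSpec,
                                  PiecewiseTrendSpec, SyntheticConfig,
                                  VariableSpec, default_coupled_config,
                                  gen_coupled_system, gen_multiscale_series,
                                  gen_trend_raster, gen_water_stack)
from hydroscale.trends import theil_sen


def _cfg(n=24, seed=0, **var):
    return SyntheticConfig(n_months=n, seed=seed, variables={"x": VariableSpec(**var)})


class TestMultiscaleSeries:
    def test_single_harmonic_extrema_count(self):
        # one 12-month tone over 24 months: 2 maxima + 2 minima inside
        cfg = _cfg(n=24, harmonics=[HarmonicSpec(12, 1.0)])
        ts = gen_multiscale_series(cfg, "x")
        mx, mn = find_extrema(ts.values)
        assert len(mx) + len(mn) == 4

    def test_pure_slope_is_strictly_increasing(self):
        cfg = _cfg(n=36, trend=PiecewiseTrendSpec(slopes=(0.01,)))
        ts = gen_multiscale_series(cfg, "x")
        assert (np.diff(ts.values) > 0).all()

    def test_determinism(self):
        cfg = _cfg(n=120, seed=42, harmonics=[HarmonicSpec(12, 1.0)],
                   noise_sd=0.5, ar1=0.4)
        a = gen_multiscale_series(cfg, "x")
        b = gen_multiscale_series(cfg, "x")
        np.testing.assert_array_equal(a.values, b.values)

    def test_ar1_autocorrelation_matches_configured_phi(self):
        phi = 0.6
        cfg = _cfg(n=480, seed=3, noise_sd=1.0, ar1=phi)
        resid = gen_multiscale_series(cfg, "x").values  # deterministic part is 0
        r1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(r1 - phi) < 0.1

    def test_piecewise_trend_is_continuous_with_reversal(self):
        spec = PiecewiseTrendSpec(breakpoints=(10,), slopes=(-1.0, 2.0), intercept=5.0)
        t = np.arange(20.0)
        v = spec.evaluate(t)
        np.testing.assert_allclose(v[:11], 5.0 - t[:11])
        np.testing.assert_allclose(np.diff(v[10:]), 2.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            HarmonicSpec(period=0, amplitude=1.0)
        with pytest.raises(ConfigError):
            PiecewiseTrendSpec(breakpoints=(5, 5), slopes=(0, 0, 0))
        with pytest.raises(ConfigError):
            CouplingSpec("p", 1.0, lag=13)
        with pytest.raises(ConfigError):
            VariableSpec(ar1=1.0)


class TestCoupledSystem:
    def test_lagged_coupling_is_exact_without_noise(self):
        cfg = SyntheticConfig(
            n_months=60, seed=0,
            variables={
                "precipitation": VariableSpec(harmonics=[HarmonicSpec(12, 5.0)],
                                              noise_sd=1.0, ar1=0.2),
                "level": VariableSpec(
                    trend=PiecewiseTrendSpec(slopes=(0.1,), intercept=2.0),
                    couplings=[CouplingSpec("precipitation", 1.0, lag=3)]),
            })
        series, _ = gen_coupled_system(cfg)
        trend = cfg.variables["level"].trend.evaluate(np.arange(60.0))
        resid = series["level"].values - trend
        p = series["precipitation"].values
        np.testing.assert_allclose(resid[3:], p[:-3], atol=1e-12)

    def test_negative_coupling_gives_negative_partial_r(self, coupled_system):
        from hydroscale.coupling import partial_correlation, transform_predictor
        cfg, series, truth = coupled_system
        trend_spec = cfg.variables["level"].trend
        y = series["level"].values - trend_spec.evaluate(np.arange(cfg.n_months, dtype=float))
        x = transform_predictor(series["ndvi"].values, 0, 3)
        ctrl = [series["temperature"].values, series["precipitation"].values]
        r, p, n = partial_correlation(y, x, ctrl)
        assert r < 0 and p < 0.01

    def test_unknown_driver_rejected(self):
        cfg = SyntheticConfig(
            n_months=60, seed=0,
            variables={"level": VariableSpec(couplings=[CouplingSpec("ghost", 1.0)])})
        with pytest.raises(ConfigError, match="ghost"):
            gen_coupled_system(cfg)

    def test_null_system_partial_r_mostly_insignificant(self):
        from hydroscale.coupling import critical_r, partial_correlation
        n, runs = 480, 200
        crit = critical_r(n, k=1)
        below = 0
        for seed in range(runs):
            cfg = SyntheticConfig(
                n_months=n, seed=seed,
                variables={v: VariableSpec(noise_sd=1.0, ar1=0.0)
                           for v in ("a", "b", "c")})
            s = {v: gen_multiscale_series(cfg, v).values for v in ("a", "b", "c")}
            r, _, _ = partial_correlation(s["a"], s["b"], [s["c"]])
            below += abs(r) < crit
        assert below / runs > 0.90  # ~95% expected under the null

    def test_ground_truth_sidecar_lists_couplings(self, coupled_system):
        _, _, truth = coupled_system
        cpl = truth["variables"]["level"]["couplings"]
        assert {c["driver"]: (c["lag"], c["accumulation"]) for c in cpl} == {
            "temperature": (0, 0), "precipitation": (3, 0), "ndvi": (0, 3)}

    def test_system_determinism(self):
        cfg1 = default_coupled_config(n_months=120, seed=5)
        cfg2 = default_coupled_config(n_months=120, seed=5)
        s1, _ = gen_coupled_system(cfg1)
        s2, _ = gen_coupled_system(cfg2)
        for name in s1:
            np.testing.assert_array_equal(s1[name].values, s2[name].values)


class TestTrendRaster:
    def test_zero_slope_zero_noise_constant(self):
        stack = gen_trend_raster((4, 4), np.zeros((4, 4)), np.zeros((4, 4)),
                                 n_months=24, seed=0)
        assert np.ptp(stack.data) == 0

    def test_noiseless_slope_recovered_exactly(self):
        slope = np.full((3, 3), 0.001)
        stack = gen_trend_raster((3, 3), slope, np.zeros((3, 3)),
                                 n_months=60, seed=0)
        s, _ = theil_sen(stack.pixel_series(1, 1))
        # centered noiseless line: variance from the target CV is entirely
        # the trend's own, so no noise is added and Sen recovers it exactly
        assert s == pytest.approx(0.001, abs=1e-12)

    def test_realized_cv_near_target(self):
        stack = gen_trend_raster((2, 2), np.zeros((2, 2)), np.full((2, 2), 0.25),
                                 n_months=240, seed=11, baseline=1.0)
        series = stack.data[:, 0, 0]
        cv = series.std(ddof=1) / series.mean()
        assert cv == pytest.approx(0.25, abs=0.05)

    def test_nonpositive_months_rejected(self):
        with pytest.raises(ConfigError):
            gen_trend_raster((2, 2), np.zeros((2, 2)), np.zeros((2, 2)),
                             n_months=0, seed=0)


class TestWaterStack:
    def test_all_permanent(self):
        stack, truth = gen_water_stack((10, 10), 24, 1.0, 0.5, seed=0)
        wet = stack.data.sum(axis=0)
        on = wet > 0
        assert truth["at_risk_fraction"] == 0.0
        assert (stack.data[:, on].min(axis=0) == 1).all()

    def test_exact_permanent_ratio(self):
        stack, truth = gen_water_stack((20, 20), 120, 0.8, 0.5, seed=1)
        assert truth["wet_ever_pixels"] == 100
        assert truth["permanent_pixels"] == 80
        assert truth["at_risk_fraction"] == pytest.approx(0.2)

    def test_fringe_occupancy_binomial_mean(self):
        stack, truth = gen_water_stack((20, 20), 240, 0.5, 0.5, seed=2)
        perm = truth["permanent_pixels"]
        freq = stack.data.mean(axis=0)
        fringe_freqs = np.sort(freq[freq > 0])[: truth["wet_ever_pixels"] - perm]
        assert np.mean(fringe_freqs) == pytest.approx(0.5, abs=0.05)

    def test_fraction_bounds_checked(self):
        with pytest.raises(ConfigError):
            gen_water_stack((4, 4), 12, 1.5, 0.5, seed=0)
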