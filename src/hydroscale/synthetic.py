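"""Synthetic monthly hydro-climatic systems with known ground truth.

This module is the test harness for the whole pipeline: it produces coupled
monthly series (temperature, precipitation, NDVI, lake level, lake area) and
raster stacks whose seasonal harmonics, multi-year oscillations,
piecewise-linear trends, AR(1) noise and lag/accumulation couplings are all
known exactly, so every downstream stage can be scored against truth.

All generation is driven by ``numpy.random.default_rng`` seeded from the
config seed plus a stable per-variable offset: the same config and seed give
bit-identical output regardless of call order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import MonthlyTimeSeries, RasterStack, YearMonth

#: maximum lag or accumulation a coupling may use; responses are generated
#: with this many burn-in months so every output month has a full window.
MAX_COUPLING_WINDOW = 12
_BURN_IN = 2 * MAX_COUPLING_WINDOW


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonicSpec:
    """One sinusoid: amplitude * sin(2*pi*t/period + phase)."""

    period: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ConfigError("harmonic period must be > 0")
        if self.amplitude < 0:
            raise ConfigError("harmonic amplitude must be >= 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.sin(2 * np.pi * t / self.period + self.phase)


@dataclass(frozen=True)
class PiecewiseTrendSpec:
    """Continuous piecewise-linear trend: one slope per segment (units/month).

    Emulates multi-stage lake histories (decline, stagnation, recovery);
    ``breakpoints`` are month indices where the slope changes.
    """

    breakpoints: tuple[int, ...] = ()
    slopes: tuple[float, ...] = (0.0,)
    intercept: float = 0.0

    def __post_init__(self) -> None:
        bps = tuple(self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ConfigError("breakpoints must be strictly increasing")
        if len(self.slopes) != len(bps) + 1:
            raise ConfigError("need exactly one slope per segment (breakpoints+1)")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, float(self.intercept))
        prev = 0.0
        level = 0.0
        bps = list(self.breakpoints) + [np.inf]
        for slope, bp in zip(self.slopes, bps):
            seg = np.clip(t, prev, bp)
            out += slope * (seg - prev)
            prev = bp
            if not np.isfinite(bp):
                break
        return out


@dataclass(frozen=True)
class CouplingSpec:
    """Linear response term: coefficient x driver accumulated then lagged.

    ``accumulation`` of m months means the rolling SUM over the window
    t-m+1..t (m of 0 or 1 both mean the raw value); ``lag`` of k months then
    shifts the result k months into the past, so the response at t sees the
    driver's window ending at t-k.
    """

    driver: str
    coefficient: float
    lag: int = 0
    accumulation: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lag <= MAX_COUPLING_WINDOW):
            raise ConfigError(f"lag must be in 0..{MAX_COUPLING_WINDOW}")
        if not (0 <= self.accumulation <= MAX_COUPLING_WINDOW):
            raise ConfigError(f"accumulation must be in 0..{MAX_COUPLING_WINDOW}")


@dataclass
class VariableSpec:
    harmonics: list[HarmonicSpec] = field(default_factory=list)
    trend: PiecewiseTrendSpec = field(default_factory=PiecewiseTrendSpec)
    noise_sd: float = 0.0
    ar1: float = 0.0
    #: if True, noise_sd is a fraction of the coupling-signal standard
    #: deviation (responses only), mirroring "noise at x% of signal" designs
    noise_relative: bool = False
    couplings: list[CouplingSpec] = field(default_factory=list)
    units: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.ar1 < 1:
            raise ConfigError("ar1 coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class SyntheticConfig:
    n_months: int
    seed: int
    start: YearMonth = field(default_factory=lambda: YearMonth(2001, 1))
    variables: dict[str, VariableSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_months < 2:
            raise ConfigError("n_months must be >= 2")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


def _rng_for(config: SyntheticConfig, variable: str) -> np.random.Generator:
    # stable per-variable stream: same variable -> same noise for a given seed
    return np.random.default_rng([config.seed % (2**31), zlib.crc32(variable.encode())])


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    w = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + w[t]
    return e


def _deterministic_part(spec: VariableSpec, t: np.ndarray) -> np.ndarray:
    out = spec.trend.evaluate(t)
    for h in spec.harmonics:
        out += h.evaluate(t)
    return out


def _accumulate_then_lag(x: np.ndarray, accumulation: int, lag: int) -> np.ndarray:
    """Full-length transform used during generation (input includes burn-in)."""
    m = max(accumulation, 1)
    acc = np.convolve(x, np.ones(m), mode="full")[: x.size]
    acc[: m - 1] = np.nan  # no full window yet
    if lag == 0:
        return acc
    out = np.full_like(acc, np.nan)
    out[lag:] = acc[:-lag]
    return out


def gen_multiscale_series(config: SyntheticConfig, variable: str) -> MonthlyTimeSeries:
    """Generate one uncoupled variable: harmonics + piecewise trend + AR(1)."""
    spec = config.variables.get(variable)
    if spec is None:
        raise ConfigError(f"variable {variable!r} not in config")
    t = np.arange(config.n_months, dtype=float)
    vals = _deterministic_part(spec, t)
    vals += _ar1_noise(_rng_for(config, variable), config.n_months, spec.noise_sd, spec.ar1)
    return MonthlyTimeSeries(start=config.start, values=vals, units=spec.units, name=variable)


def gen_coupled_system(
    config: SyntheticConfig,
) -> tuple[dict[str, MonthlyTimeSeries], dict]:
    """Generate the full coupled variable set plus its ground truth.

    Driver variables (no couplings) are generated first with a burn-in period
    so response windows are complete from the first output month; each
    response is the sum of its coupling terms, its own trend/harmonics, and
    AR(1) noise. Returns ``(series by name, ground-truth dict)``; the ground
    truth records every coupling (driver, coefficient, lag, accumulation) and
    trend so recovery tests are self-contained.
    """
    n = config.n_months
    n_full = n + _BURN_IN
    t_full = np.arange(n_full, dtype=float) - _BURN_IN  # output months at t>=0

    drivers = {name: spec for name, spec in config.variables.items() if not spec.couplings}
    responses = {name: spec for name, spec in config.variables.items() if spec.couplings}
    for name, spec in responses.items():
        for c in spec.couplings:
            if c.driver not in drivers:
                raise ConfigError(f"{name}: coupling references unknown driver {c.driver!r}")

    full: dict[str, np.ndarray] = {}
    for name, spec in drivers.items():
        vals = _deterministic_part(spec, t_full)
        vals += _ar1_noise(_rng_for(config, name), n_full, spec.noise_sd, spec.ar1)
        full[name] = vals

    out: dict[str, MonthlyTimeSeries] = {}
    for name in drivers:
        out[name] = MonthlyTimeSeries(
            start=config.start, values=full[name][_BURN_IN:],
            units=config.variables[name].units, name=name)

    for name, spec in responses.items():
        signal = np.zeros(n_full)
        for c in spec.couplings:
            term = c.coefficient * _accumulate_then_lag(full[c.driver], c.accumulation, c.lag)
            signal += term
        signal_out = signal[_BURN_IN:]
        assert np.isfinite(signal_out).all()  # burn-in guarantees full windows
        sd_noise = spec.noise_sd
        if spec.noise_relative:
            sd_noise = spec.noise_sd * float(np.std(signal_out))
        vals = signal_out + _deterministic_part(spec, np.arange(n, dtype=float))
        vals += _ar1_noise(_rng_for(config, name), n, sd_noise, spec.ar1)
        out[name] = MonthlyTimeSeries(start=config.start, values=vals,
                                      units=spec.units, name=name)

    truth = ground_truth(config)
    return out, truth


def ground_truth(config: SyntheticConfig) -> dict:
    """JSON-serializable ground-truth sidecar for a config."""
    return {
        "n_months": config.n_months,
        "seed": config.seed,
        "start": str(config.start),
        "variables": {
            name: {
                "harmonics": [asdict(h) for h in spec.harmonics],
                "trend": {
                    "breakpoints": list(spec.trend.breakpoints),
                    "slopes": list(spec.trend.slopes),
                    "intercept": spec.trend.intercept,
                },
                "noise_sd": spec.noise_sd,
                "ar1": spec.ar1,
                "noise_relative": spec.noise_relative,
                "couplings": [asdict(c) for c in spec.couplings],
                "units": spec.units,
            }
            for name, spec in config.variables.items()
        },
    }


def write_ground_truth(config: SyntheticConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth(config), indent=1))


# ---------------------------------------------------------------------------
# study-condition defaults

#: phases putting the seasonal peak of each driver at its climatological
#: month (temperature/NDVI peak July, precipitation peak June)
_PHASE_PEAK_JULY = np.pi / 2 - 2 * np.pi * 6 / 12
_PHASE_PEAK_JUNE = np.pi / 2 - 2 * np.pi * 5 / 12


def default_coupled_config(n_months: int = 480, seed: int = 0,
                           response_noise: float = 0.3) -> SyntheticConfig:
    """The package's reference coupled system.

    An arid-watershed monthly climate: strong temperature seasonality
    (~15 degC amplitude) with small weather anomalies, summer-concentrated
    precipitation with large relative variability, a vegetated NDVI cycle
    around 0.25, and a lake whose level/area respond to temperature
    synchronously (+), to precipitation with a 3-month lag (+), and to
    3-month-accumulated NDVI negatively — with a decline/stable/recovery
    piecewise trend. ``response_noise`` is the response AR(1) noise standard
    deviation as a fraction of the coupling-signal standard deviation.
    """
    third = n_months // 3
    lake_trend = dict(breakpoints=(third, 2 * third))
    cfg = SyntheticConfig(
        n_months=n_months, seed=seed,
        variables={
            "temperature": VariableSpec(
                harmonics=[HarmonicSpec(12, 15.0, _PHASE_PEAK_JULY),
                           HarmonicSpec(60, 0.8)],
                trend=PiecewiseTrendSpec(intercept=8.0),
                noise_sd=2.0, ar1=0.3, units="degC"),
            "precipitation": VariableSpec(
                harmonics=[HarmonicSpec(12, 12.0, _PHASE_PEAK_JUNE),
                           HarmonicSpec(60, 3.0)],
                trend=PiecewiseTrendSpec(intercept=16.0, slopes=(0.007,)),
                noise_sd=8.0, ar1=0.2, units="mm"),
            "ndvi": VariableSpec(
                harmonics=[HarmonicSpec(12, 0.12, _PHASE_PEAK_JULY),
                           HarmonicSpec(60, 0.02)],
                trend=PiecewiseTrendSpec(intercept=0.25),
                noise_sd=0.03, ar1=0.3, units="NDVI"),
            "level": VariableSpec(
                trend=PiecewiseTrendSpec(slopes=(-0.06, 0.0, 0.005), intercept=1048.0,
                                         **lake_trend),
                couplings=[CouplingSpec("temperature", +0.050, lag=0, accumulation=0),
                           CouplingSpec("precipitation", +0.020, lag=3, accumulation=0),
                           CouplingSpec("ndvi", -1.2, lag=0, accumulation=3)],
                noise_sd=response_noise, noise_relative=True, ar1=0.3, units="m"),
            "area": VariableSpec(
                trend=PiecewiseTrendSpec(slopes=(-1.6, 0.0, 0.14), intercept=1000.0,
                                         **lake_trend),
                couplings=[CouplingSpec("temperature", +2.5, lag=0, accumulation=0),
                           CouplingSpec("precipitation", +1.0, lag=3, accumulation=0),
                           CouplingSpec("ndvi", -60.0, lag=0, accumulation=3)],
                noise_sd=response_noise, noise_relative=True, ar1=0.3, units="km2"),
        },
    )
    return cfg


# ---------------------------------------------------------------------------
# raster generators


def gen_trend_raster(shape: tuple[int, int], slope_field: np.ndarray,
                     cv_target_field: np.ndarray, n_months: int, seed: int,
                     baseline: float = 1.0,
                     start: YearMonth = YearMonth(2001, 1)) -> RasterStack:
    """Per-pixel linear trends with noise scaled to hit a target CV.

    Each pixel's series is ``baseline + slope*(t - (n-1)/2) + white noise``;
    centering the trend keeps the pixel mean at ``baseline`` exactly, so the
    white-noise standard deviation can be solved from the target CV after
    subtracting the variance the trend itself contributes.
    """
    if n_months <= 0:
        raise ConfigError("n_months must be positive")
    rows, cols = shape
    slope_field = np.broadcast_to(np.asarray(slope_field, dtype=float), shape)
    cv_field = np.broadcast_to(np.asarray(cv_target_field, dtype=float), shape)
    t = np.arange(n_months, dtype=float) - (n_months - 1) / 2.0
    rng = np.random.default_rng(seed)
    # variance of the centered linear term over the sampled months
    var_trend = slope_field**2 * np.mean(t**2)
    var_total = (cv_field * baseline) ** 2
    noise_sd = np.sqrt(np.clip(var_total - var_trend, 0.0, None))
    data = baseline + slope_field[None] * t[:, None, None]
    data += rng.normal(0.0, 1.0, size=(n_months, rows, cols)) * noise_sd[None]
    return RasterStack(data=data, start=start)


def gen_water_stack(shape: tuple[int, int], n_months: int,
                    permanent_fraction: float, fringe_occupancy: float, seed: int,
                    start: YearMonth = YearMonth(2001, 1)) -> tuple[RasterStack, dict]:
    """Binary water stack: a contiguous permanent core plus a seasonal fringe.

    The wet-ever region is a centered rectangle of (rows//2) x (cols//2)
    pixels; the innermost ``round(permanent_fraction * wet_ever)`` pixels
    (by Chebyshev distance from the center, ties broken row-major) are water
    every month. Fringe pixels are wet in each month independently with
    probability ``fringe_occupancy`` but are forced to have at least one wet
    and one dry month, so "permanent <=> frequency 100%" holds exactly and the
    at-risk fraction equals ``1 - permanent/wet_ever`` by construction.
    """
    for frac, label in ((permanent_fraction, "permanent_fraction"),
                        (fringe_occupancy, "fringe_occupancy")):
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"{label} must be in [0, 1]")
    rows, cols = shape
    h, w = max(rows // 2, 1), max(cols // 2, 1)
    r0, c0 = (rows - h) // 2, (cols - w) // 2
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    wet_ever = (rr >= r0) & (rr < r0 + h) & (cc >= c0) & (cc < c0 + w)
    n_wet = int(wet_ever.sum())
    n_perm = int(round(permanent_fraction * n_wet))
    # order wet-ever pixels inside-out so the permanent core is contiguous
    cy, cx = r0 + (h - 1) / 2.0, c0 + (w - 1) / 2.0
    dist = np.maximum(np.abs(rr - cy), np.abs(cc - cx))
    wet_idx = np.flatnonzero(wet_ever.ravel())
    order = wet_idx[np.argsort(dist.ravel()[wet_idx], kind="stable")]
    perm_idx, fringe_idx = order[:n_perm], order[n_perm:]

    rng = np.random.default_rng(seed)
    data = np.zeros((n_months, rows, cols))
    flat = data.reshape(n_months, -1)
    flat[:, perm_idx] = 1.0
    if fringe_idx.size:
        wet = rng.random((n_months, fringe_idx.size)) < fringe_occupancy
        # force at least one wet and one dry month per fringe pixel
        all_dry = ~wet.any(axis=0)
        wet[rng.integers(0, n_months, size=fringe_idx.size)[all_dry], np.flatnonzero(all_dry)] = True
        all_wet = wet.all(axis=0)
        wet[rng.integers(0, n_months, size=fringe_idx.size)[all_wet], np.flatnonzero(all_wet)] = False
        flat[:, fringe_idx] = wet.astype(float)
    truth = {
        "wet_ever_pixels": n_wet,
        "permanent_pixels": n_perm,
        "at_risk_fraction": (n_wet - n_perm) / n_wet if n_wet else 0.0,
        "fringe_occupancy": fringe_occupancy,
    }
    return RasterStack(data=data, start=start), truth
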