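"""Robust trends, variability and water-frequency statistics, scalar and per-pixel.

Theil-Sen median slope and the Mann-Kendall test are the standard
nonparametric pair for monotone-trend mapping of remote-sensing monthlies;
the coefficient of variation (sample sd / mean) with its five-class
volatility legend quantifies interannual NDVI variability; water frequency
(percent of months a pixel is water) separates permanent from seasonal
surface water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (CalendarWindow, DataQualityError, FULL_YEAR, GROWING_SEASON,
                   InputFormatError, MonthlyTimeSeries, RasterStack,
                   seasonal_yearly_means)

#: NDVI slope classification threshold, units NDVI/year
SLOPE_THRESHOLD = 0.0005

#: CV class lower bounds (inclusive), highest first
CV_CLASSES: list[tuple[float, str]] = [
    (0.20, "High volatility"),
    (0.15, "Relative-high volatility"),
    (0.10, "Medium volatility"),
    (0.05, "Relatively low volatility"),
    (0.00, "Low volatility"),
]

TREND_CLASSES = ("improved", "stable", "degraded")

#: pixels missing in more than this fraction of time steps are excluded
MAX_PIXEL_MISSING_FRACTION = 0.10


@dataclass
class TrendResult:
    sen_slope: float          # units per month
    sen_slope_annual: float   # units per year (12x monthly)
    mk_s: int
    mk_var_s: float
    mk_z: float
    mk_p: float
    n: int


@dataclass
class CvResult:
    cv: float
    class_label: str
    n: int


@dataclass
class ClassMap:
    labels: np.ndarray           # 2-D object array of class names ('' invalid)
    percentages: dict[str, float]  # class -> % of valid pixels (sums to 100)
    valid: np.ndarray            # boolean 2-D


@dataclass
class FrequencyMap:
    frequency: np.ndarray        # 2-D, percent of valid months wet (NaN off-water-grid)
    wet_ever: np.ndarray         # boolean
    permanent: np.ndarray        # boolean, frequency exactly 100
    at_risk_fraction: float      # wet-ever pixels with 0 < freq < 100, as a fraction


# ---------------------------------------------------------------------------
# scalar statistics


def _observed(ts) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ts, MonthlyTimeSeries):
        return ts.observed()
    v = np.asarray(ts, dtype=float)
    t = np.arange(v.size, dtype=float)
    keep = np.isfinite(v)
    return t[keep], v[keep]


def theil_sen(ts) -> tuple[float, float]:
    """Median of all pairwise slopes over month indices.

    Returns (slope per month, slope per year); missing entries are skipped
    but their calendar position is kept, so gaps do not distort the time
    axis.
    """
    t, v = _observed(ts)
    n = v.size
    if n < 3:
        raise DataQualityError("Theil-Sen needs at least 3 observed values")
    dt = t[None, :] - t[:, None]
    dv = v[None, :] - v[:, None]
    iu = np.triu_indices(n, k=1)
    slope = float(np.median(dv[iu] / dt[iu]))
    return slope, 12.0 * slope


def mann_kendall(ts) -> TrendResult:
    """Mann-Kendall monotone-trend test with tie-corrected variance.

    S sums the signs of all forward differences; Var(S) applies the usual
    tie-group correction; z uses the +/-1 continuity correction and the
    p-value is two-sided normal.
    """
    t, v = _observed(ts)
    n = v.size
    if n < 4:
        raise DataQualityError("Mann-Kendall needs at least 4 observed values")
    diff = np.sign(v[None, :] - v[:, None])
    iu = np.triu_indices(n, k=1)
    s = int(np.sum(diff[iu]))
    _, counts = np.unique(v, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values tied
        return TrendResult(*theil_sen(ts), mk_s=0, mk_var_s=0.0, mk_z=0.0, mk_p=1.0, n=n)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    slope, slope_y = theil_sen(ts)
    return TrendResult(sen_slope=slope, sen_slope_annual=slope_y, mk_s=s,
                       mk_var_s=float(var_s), mk_z=float(z), mk_p=float(p), n=n)


def classify_trend(annual_slope: float, threshold: float = SLOPE_THRESHOLD) -> str:
    """improved / stable / degraded by annualized Sen slope.

    The class boundaries overlap at exactly +threshold under the usual
    inclusive conventions; the improved class takes precedence there.
    """
    if not np.isfinite(annual_slope):
        raise ValueError("slope must be finite")
    if annual_slope >= threshold:
        return "improved"
    if annual_slope < -threshold:
        return "degraded"
    return "stable"


def coefficient_of_variation(values) -> CvResult:
    """Sample CV (sd with n-1 / mean) with the five-class volatility label."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise DataQualityError("CV needs at least 3 values")
    mean = v.mean()
    if mean <= 0:
        raise DataQualityError("CV undefined for non-positive mean")
    cv = float(v.std(ddof=1) / mean)
    return CvResult(cv=cv, class_label=classify_cv(cv), n=v.size)


def classify_cv(cv: float) -> str:
    for lower, label in CV_CLASSES:
        if cv >= lower:
            return label
    return CV_CLASSES[-1][1]


def cv_yearly(ts: MonthlyTimeSeries, window: CalendarWindow = GROWING_SEASON) -> CvResult:
    """CV over yearly growing-season means (the interannual-variability mode)."""
    _, means = seasonal_yearly_means(ts, window)
    return coefficient_of_variation(means)


# ---------------------------------------------------------------------------
# raster operations


def _valid_pixels(stack: RasterStack) -> np.ndarray:
    missing_frac = stack.nodata.mean(axis=0)
    return missing_frac <= MAX_PIXEL_MISSING_FRACTION


def vegetation_mask(ndvi_stack: RasterStack, window: CalendarWindow = GROWING_SEASON,
                    threshold: float = 0.1, rule: str = "every_year") -> np.ndarray:
    """Stable-vegetation mask: growing-season NDVI >= threshold (inclusive).

    ``every_year`` demands the growing-season mean clear the threshold in
    every observed year; ``mean_of_years`` only on average.
    """
    in_window = ndvi_stack.window_mask(window)
    if not in_window.any():
        raise DataQualityError("stack does not cover the requested window")
    months = ndvi_stack.calendar_months()
    years = np.array([ym.year for ym in ndvi_stack.months()])
    if window.wraps:
        years = years - (months <= window.last_month)
    data = np.where(ndvi_stack.nodata, np.nan, ndvi_stack.data)
    yearly = []
    for y in np.unique(years[in_window]):
        sel = in_window & (years == y)
        with np.errstate(invalid="ignore"):
            yearly.append(np.nanmean(data[sel], axis=0))
    yearly = np.stack(yearly)
    # inclusive threshold with absolute round-off slack: averaging exactly
    # threshold-valued samples must not fall below it by one ulp
    thr = threshold - 1e-12
    with np.errstate(invalid="ignore"):
        if rule == "every_year":
            out = np.nanmin(yearly, axis=0) >= thr
        elif rule == "mean_of_years":
            out = np.nanmean(yearly, axis=0) >= thr
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return out & np.isfinite(yearly).any(axis=0)


def water_frequency(water_stack: RasterStack,
                    window: CalendarWindow = FULL_YEAR) -> FrequencyMap:
    """Per-pixel percentage of valid in-window months classified as water."""
    data = water_stack.data
    valid = ~water_stack.nodata
    vals = data[valid]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise InputFormatError("water stack must be binary {0,1}")
    sel = water_stack.window_mask(window)
    wet = np.where(valid, data, 0.0)[sel].sum(axis=0)
    n_valid = valid[sel].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = 100.0 * wet / n_valid
    freq[n_valid == 0] = np.nan
    wet_ever = wet > 0
    permanent = wet_ever & (wet == n_valid)
    n_wet_ever = int(wet_ever.sum())
    at_risk = int((wet_ever & ~permanent).sum()) / n_wet_ever if n_wet_ever else 0.0
    freq = np.where(wet_ever, freq, np.nan)
    return FrequencyMap(frequency=freq, wet_ever=wet_ever, permanent=permanent,
                        at_risk_fraction=at_risk)


def _class_percentages(labels: np.ndarray, valid: np.ndarray,
                       legend: tuple[str, ...]) -> dict[str, float]:
    n_valid = int(valid.sum())
    out = {}
    for name in legend:
        count = int(((labels == name) & valid).sum())
        out[name] = 100.0 * count / n_valid if n_valid else 0.0
    return out


def pixelwise(op: str, stack: RasterStack, mask: np.ndarray | None = None,
              window: CalendarWindow = GROWING_SEASON,
              slope_threshold: float = SLOPE_THRESHOLD) -> dict:
    """Apply a scalar statistic per pixel and classify the result.

    ``op`` is one of ``theil_sen``, ``mann_kendall``, ``cv``. Pixels missing
    in more than 10% of time steps (or outside ``mask``) are excluded; class
    percentages are over valid pixels and always sum to 100.
    """
    if op not in ("theil_sen", "mann_kendall", "cv"):
        raise ValueError(f"unknown pixelwise op {op!r}")
    rows, cols = stack.shape
    valid = _valid_pixels(stack)
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    maps: dict[str, np.ndarray] = {}

    def nanmap() -> np.ndarray:
        return np.full((rows, cols), np.nan)

    if op in ("theil_sen", "mann_kendall"):
        maps["sen_slope"] = nanmap()
        maps["sen_slope_annual"] = nanmap()
    if op == "mann_kendall":
        maps["mk_z"] = nanmap()
        maps["mk_p"] = nanmap()
    if op == "cv":
        maps["cv"] = nanmap()

    labels = np.full((rows, cols), "", dtype=object)
    for r in range(rows):
        for col in range(cols):
            if not valid[r, col]:
                continue
            series = stack.pixel_series(r, col)
            try:
                if op == "cv":
                    res = cv_yearly(series, window)
                    maps["cv"][r, col] = res.cv
                    labels[r, col] = res.class_label
                elif op == "theil_sen":
                    s, sy = theil_sen(series)
                    maps["sen_slope"][r, col] = s
                    maps["sen_slope_annual"][r, col] = sy
                    labels[r, col] = classify_trend(sy, slope_threshold)
                else:
                    res = mann_kendall(series)
                    maps["sen_slope"][r, col] = res.sen_slope
                    maps["sen_slope_annual"][r, col] = res.sen_slope_annual
                    maps["mk_z"][r, col] = res.mk_z
                    maps["mk_p"][r, col] = res.mk_p
                    labels[r, col] = classify_trend(res.sen_slope_annual, slope_threshold)
            except DataQualityError:
                valid[r, col] = False
    legend = tuple(lbl for _, lbl in CV_CLASSES) if op == "cv" else TREND_CLASSES
    class_map = ClassMap(labels=labels, valid=valid,
                         percentages=_class_percentages(labels, valid, legend))
    return {"maps": maps, "classes": class_map, "valid": valid}
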