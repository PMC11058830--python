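"""Lag/accumulation partial-correlation coupling between lake and drivers.

The response of a lake to its drivers is rarely instantaneous: precipitation
may act with a lag of some months (TL-k), and a driver may matter through
its running total over a window (TA-m). This module evaluates the partial
correlation of a response against every (lag, accumulation) transform of a
predictor on a small grid — controlling for the remaining drivers — and
reports the best combination.

Because the best cell is selected as the maximum of many correlated tests,
its p-value is optimistically biased; every grid carries an explicit
``selection_bias_note`` and downstream reports must print it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DataQualityError, MonthlyTimeSeries, YearMonth
from .eemd import ScaleComponents

SELECTION_BIAS_NOTE = (
    "best-cell p-values are selection-biased: the reported combination "
    "maximizes |r| over the whole lag/accumulation grid")


@dataclass
class LagAccumGrid:
    response: str
    predictor: str
    controls: list[str]
    r: np.ndarray          # (max_lag+1, max_accum+1)
    p: np.ndarray
    n_effective: np.ndarray
    best_lag: int
    best_accum: int
    best_r: float
    best_p: float
    selection_bias_note: str = SELECTION_BIAS_NOTE


@dataclass
class SeasonalCurve:
    """Twelve calendar-month values normalized so sum(|values|) = 1."""

    values: np.ndarray      # index 0 = January
    normalization: float    # the sum of absolute month means divided out


# ---------------------------------------------------------------------------
# elementary transforms


def _as_values(x) -> np.ndarray:
    if isinstance(x, MonthlyTimeSeries):
        v = x.values.copy()
        v[x.missing] = np.nan
        return v
    return np.asarray(x, dtype=float).copy()


def lag_series(x, k: int) -> np.ndarray:
    """Shift so position t holds the value at t-k; first k entries NaN."""
    v = _as_values(x)
    if k < 0:
        raise ValueError("lag must be >= 0")
    if k >= v.size:
        raise ValueError(f"lag {k} >= series length {v.size}")
    if k == 0:
        return v
    out = np.full_like(v, np.nan)
    out[k:] = v[:-k]
    return out


def accumulate_series(x, m: int) -> np.ndarray:
    """Rolling SUM over the m-month window ending at t; first m-1 entries NaN.

    m of 0 and 1 both mean the raw value (a one-month window); correlation is
    scale-invariant, so a sum (rather than mean) convention changes nothing
    downstream.
    """
    v = _as_values(x)
    if m < 0:
        raise ValueError("accumulation must be >= 0")
    if m >= v.size and m > 1:
        raise ValueError(f"accumulation {m} >= series length {v.size}")
    if m <= 1:
        return v
    out = np.convolve(v, np.ones(m), mode="full")[: v.size]
    out[: m - 1] = np.nan
    return out


def transform_predictor(x, lag: int, accumulation: int) -> np.ndarray:
    """Accumulate over the window, then shift the window end k months back."""
    return lag_series(accumulate_series(x, accumulation), lag)


# ---------------------------------------------------------------------------
# partial correlation


def partial_correlation(y, x, controls: list | tuple = ()) -> tuple[float, float, int]:
    """Partial r of y and x given controls, by OLS residualization.

    Both y and x are regressed on the controls (with intercept); r is the
    Pearson correlation of the residuals, and the p-value comes from
    t = r*sqrt(df/(1-r^2)) with df = n - 2 - #controls, two-sided. With no
    controls this is plain Pearson correlation. Rows with any NaN are
    dropped pairwise.
    """
    yv = _as_values(y)
    xv = _as_values(x)
    cv = [_as_values(c) for c in controls]
    if any(a.size != yv.size for a in [xv, *cv]):
        raise ValueError("all sequences must share one monthly index")
    keep = np.isfinite(yv) & np.isfinite(xv)
    for c in cv:
        keep &= np.isfinite(c)
    n = int(keep.sum())
    k = len(cv)
    df = n - 2 - k
    if df < 1:
        raise DataQualityError(f"n={n} too small for {k} controls")
    yv, xv = yv[keep], xv[keep]
    design = np.column_stack([np.ones(n)] + [c[keep] for c in cv])
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    sy, sx = np.std(ry), np.std(rx)
    # residuals smaller than numerical noise mean the variable was (an affine
    # function of) the controls: the partial correlation is undefined
    tol_y = 1e-10 * max(np.std(yv), 1e-30)
    tol_x = 1e-10 * max(np.std(xv), 1e-30)
    if sy <= tol_y or sx <= tol_x:
        return np.nan, np.nan, n
    r = float(np.dot(ry, rx) / (n * sy * sx))
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p), n


def critical_r(n: int, k: int = 0, alpha: float = 0.05) -> float:
    """|r| needed for two-sided significance at alpha with k controls."""
    df = n - 2 - k
    tc = stats.t.isf(alpha / 2.0, df)
    return float(tc / np.sqrt(df + tc * tc))


# ---------------------------------------------------------------------------
# grid search


def _best_cell(r: np.ndarray, n_eff: np.ndarray, min_n: int) -> tuple[int, int]:
    """Max |r| among admissible cells; ties to smaller lag+accum, then lag."""
    best = None
    for lag in range(r.shape[0]):
        for acc in range(r.shape[1]):
            if n_eff[lag, acc] < min_n or not np.isfinite(r[lag, acc]):
                continue
            key = (-abs(r[lag, acc]), lag + acc, lag)
            if best is None or key < best[0]:
                best = (key, lag, acc)
    if best is None:
        raise DataQualityError(f"no grid cell reaches min_n={min_n} valid months")
    return best[1], best[2]


def tl_ta_search(response, predictor, controls: list | tuple = (),
                 max_lag: int = 3, max_accum: int = 3, min_n: int = 24,
                 controls_mode: str = "best",
                 response_name: str = "response", predictor_name: str = "predictor",
                 control_names: list[str] | None = None) -> LagAccumGrid:
    """Partial-r surface over every (lag, accumulation) of the predictor.

    Controls enter either untransformed (``controls_mode='raw'``) or at their
    own best (lag, accumulation) against the response found in a first
    plain-correlation pass (``'best'``, the default), then held fixed.
    """
    yv = _as_values(response)
    xv = _as_values(predictor)
    ctrl = [_as_values(c) for c in controls]
    if controls_mode == "best":
        fixed = []
        for c in ctrl:
            lag_c, acc_c = _control_best(yv, c, max_lag, max_accum, min_n)
            fixed.append(transform_predictor(c, lag_c, acc_c))
        ctrl = fixed
    elif controls_mode != "raw":
        raise ValueError(f"unknown controls_mode {controls_mode!r}")
    shape = (max_lag + 1, max_accum + 1)
    r = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    n_eff = np.zeros(shape, dtype=int)
    for lag in range(max_lag + 1):
        for acc in range(max_accum + 1):
            xt = transform_predictor(xv, lag, acc)
            try:
                r[lag, acc], p[lag, acc], n_eff[lag, acc] = partial_correlation(yv, xt, ctrl)
            except DataQualityError:
                continue
    bl, ba = _best_cell(r, n_eff, min_n)
    return LagAccumGrid(response=response_name, predictor=predictor_name,
                        controls=list(control_names or []),
                        r=r, p=p, n_effective=n_eff,
                        best_lag=bl, best_accum=ba,
                        best_r=float(r[bl, ba]), best_p=float(p[bl, ba]))


def _control_best(yv: np.ndarray, c: np.ndarray, max_lag: int, max_accum: int,
                  min_n: int) -> tuple[int, int]:
    shape = (max_lag + 1, max_accum + 1)
    r = np.full(shape, np.nan)
    n_eff = np.zeros(shape, dtype=int)
    for lag in range(max_lag + 1):
        for acc in range(max_accum + 1):
            ct = transform_predictor(c, lag, acc)
            try:
                r[lag, acc], _, n_eff[lag, acc] = partial_correlation(yv, ct, ())
            except DataQualityError:
                continue
    return _best_cell(r, n_eff, min_n)


def joint_tl_ta_search(response, predictors: dict[str, np.ndarray],
                       max_lag: int = 3, max_accum: int = 3, min_n: int = 24,
                       n_iterations: int = 2,
                       response_name: str = "response") -> dict[str, LagAccumGrid]:
    """Estimate every predictor's best (lag, accumulation) jointly.

    When drivers share seasonal phase, a single grid pass with untransformed
    controls misattributes their overlap. This backfitting scheme fixes that:
    each predictor's grid is searched with the *other* predictors controlled
    at their current best transforms, starting from untransformed controls
    and sweeping the predictor set ``n_iterations`` times (one initial pass
    plus ``n_iterations - 1`` refinements). Deterministic: predictors are
    swept in sorted-name order.
    """
    names = sorted(predictors)
    raw = {q: _as_values(predictors[q]) for q in names}
    current: dict[str, tuple[int, int]] = {q: (0, 0) for q in names}
    grids: dict[str, LagAccumGrid] = {}
    for _ in range(max(n_iterations, 1)):
        for pred in names:
            others = [q for q in names if q != pred]
            ctrl = [transform_predictor(raw[q], *current[q]) for q in others]
            grid = tl_ta_search(response, raw[pred], ctrl,
                                max_lag=max_lag, max_accum=max_accum,
                                min_n=min_n, controls_mode="raw",
                                response_name=response_name,
                                predictor_name=pred, control_names=others)
            current[pred] = (grid.best_lag, grid.best_accum)
            grids[pred] = grid
    return grids


# ---------------------------------------------------------------------------
# component-level coupling tables


def component_coupling(components: dict[str, ScaleComponents], component: str,
                       response: str, predictors: list[str],
                       max_lag: int = 3, max_accum: int = 3, min_n: int = 24,
                       controls_mode: str = "joint") -> list[LagAccumGrid]:
    """Best TL/TA partial correlation of a response component per predictor.

    For the chosen scale component (``annual`` or ``interannual``) of every
    variable, runs the grid search of the response against each predictor
    with the remaining predictors as controls — one row per predictor, the
    structural analogue of a per-timescale coupling table. ``controls_mode``
    ``'joint'`` (default) backfits all predictors' transforms together,
    which is the robust choice when drivers share seasonal phase; ``'best'``
    and ``'raw'`` fall through to :func:`tl_ta_search`.
    """
    if component not in ("annual", "interannual", "noise"):
        raise ValueError(f"unknown component {component!r}")
    attr = f"c_{component}"
    series = {name: getattr(sc, attr) for name, sc in components.items()}
    lengths = {v.size for v in series.values()}
    if len(lengths) != 1:
        raise DataQualityError("all variables must share one monthly index")
    if controls_mode == "joint":
        grids = joint_tl_ta_search(series[response],
                                   {q: series[q] for q in predictors},
                                   max_lag=max_lag, max_accum=max_accum,
                                   min_n=min_n, response_name=response)
        return [grids[q] for q in predictors]
    out = []
    for pred in predictors:
        ctrl_names = [q for q in predictors if q != pred]
        grid = tl_ta_search(series[response], series[pred],
                            [series[q] for q in ctrl_names],
                            max_lag=max_lag, max_accum=max_accum, min_n=min_n,
                            controls_mode=controls_mode,
                            response_name=response, predictor_name=pred,
                            control_names=ctrl_names)
        out.append(grid)
    return out


def seasonal_curve(c_annual, start: YearMonth) -> SeasonalCurve:
    """Calendar-month means of an annual component, amplitude-normalized.

    Averages the component by calendar month across all full years, then
    divides by the sum of absolute month means so curves of variables with
    different units and amplitudes are directly comparable.
    """
    v = np.asarray(c_annual, dtype=float)
    if v.size < 24:
        raise DataQualityError("seasonal curve needs at least 2 full years")
    months = (start.month - 1 + np.arange(v.size)) % 12
    means = np.array([v[months == m].mean() for m in range(12)])
    norm = float(np.sum(np.abs(means)))
    if norm == 0:
        raise DataQualityError("component is identically zero")
    return SeasonalCurve(values=means / norm, normalization=norm)
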