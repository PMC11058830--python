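"""Shared data model: monthly time series, raster stacks, calendar windows, I/O.

The atomic time unit throughout the package is the calendar month: series are
stored against a contiguous monthly index and days are never represented.
Missing observations are an explicit boolean mask (never sentinel values), so
downstream statistics can skip or refuse deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class InputFormatError(ValueError):
    """Raised when an on-disk input cannot be parsed into the data model."""


class DataQualityError(ValueError):
    """Raised when an input parses but violates a quality precondition."""


# ---------------------------------------------------------------------------
# calendar helpers


@dataclass(frozen=True)
class YearMonth:
    """A calendar month (year, month 1-12)."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    def to_index(self) -> int:
        return self.year * 12 + (self.month - 1)

    @classmethod
    def from_index(cls, idx: int) -> "YearMonth":
        return cls(idx // 12, idx % 12 + 1)

    def plus(self, months: int) -> "YearMonth":
        return YearMonth.from_index(self.to_index() + months)

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    @classmethod
    def parse(cls, text: str) -> "YearMonth":
        s = str(text).strip()
        for fmt in ("%Y-%m", "%Y/%m", "%Y-%m-%d", "%Y/%m/%d", "%Y%m"):
            try:
                ts = pd.to_datetime(s, format=fmt)
                return cls(int(ts.year), int(ts.month))
            except (ValueError, TypeError):
                continue
        raise InputFormatError(f"cannot parse {text!r} as a year-month")


@dataclass(frozen=True)
class CalendarWindow:
    """Inclusive month-of-year window; wrapping (e.g. Nov-Feb) is allowed.

    The growing season used throughout the vegetation analyses is March-October.
    """

    first_month: int = 3
    last_month: int = 10

    def __post_init__(self) -> None:
        for m in (self.first_month, self.last_month):
            if not 1 <= m <= 12:
                raise ValueError(f"window months must be in 1..12, got {m}")

    @property
    def wraps(self) -> bool:
        return self.last_month < self.first_month

    def contains(self, month: int) -> bool:
        if self.wraps:
            return month >= self.first_month or month <= self.last_month
        return self.first_month <= month <= self.last_month

    def months(self) -> list[int]:
        if self.wraps:
            return list(range(self.first_month, 13)) + list(range(1, self.last_month + 1))
        return list(range(self.first_month, self.last_month + 1))


GROWING_SEASON = CalendarWindow(3, 10)
FULL_YEAR = CalendarWindow(1, 12)


# ---------------------------------------------------------------------------
# monthly time series


@dataclass
class MonthlyTimeSeries:
    """Regularly spaced monthly observations of one variable.

    ``values[i]`` belongs to calendar month ``start + i``; gaps in the record
    are represented in-band as ``missing=True`` entries, never by omitting the
    month from the index.
    """

    start: YearMonth
    values: np.ndarray
    units: str = ""
    name: str = ""
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a monthly series needs a 1-D array of length >= 2")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask must match values length")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def n_observed(self) -> int:
        return int((~self.missing).sum())

    def month_index(self) -> np.ndarray:
        """Integer month offsets 0..n-1 (the regression time axis)."""
        return np.arange(len(self), dtype=float)

    def months(self) -> list[YearMonth]:
        return [self.start.plus(i) for i in range(len(self))]

    def calendar_months(self) -> np.ndarray:
        """Month-of-year (1..12) for every entry."""
        m0 = self.start.month - 1
        return (m0 + np.arange(len(self))) % 12 + 1

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(month offsets, values) of the non-missing entries."""
        keep = ~self.missing
        return self.month_index()[keep], self.values[keep]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "MonthlyTimeSeries":
        return MonthlyTimeSeries(
            start=self.start,
            values=np.asarray(values, dtype=float),
            units=self.units,
            name=self.name if name is None else name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [str(m) for m in self.months()],
                "value": np.where(self.missing, np.nan, self.values),
            }
        )


def read_series_csv(
    path: str | Path, date_column: str = "date", value_column: str = "value",
    units: str = "", name: str = "",
) -> MonthlyTimeSeries:
    """Read one monthly series from CSV, padding absent months as missing.

    Dates must parse as year-month (``YYYY-MM`` preferred); a duplicated month
    is an error rather than silently aggregated.
    """
    df = pd.read_csv(path)
    for col in (date_column, value_column):
        if col not in df.columns:
            raise InputFormatError(f"{path}: column {col!r} not found")
    if len(df) < 2:
        raise InputFormatError(f"{path}: need at least 2 rows")
    idx = np.array([YearMonth.parse(d).to_index() for d in df[date_column]])
    if np.unique(idx).size != idx.size:
        dup = YearMonth.from_index(int(idx[np.argmax(np.bincount(idx - idx.min()) > 1)]))
        raise InputFormatError(f"{path}: duplicate month in {date_column} (e.g. {dup})")
    order = np.argsort(idx)
    idx = idx[order]
    vals = pd.to_numeric(df[value_column], errors="coerce").to_numpy()[order]
    n = int(idx[-1] - idx[0]) + 1
    full = np.full(n, np.nan)
    full[idx - idx[0]] = vals
    name = name or str(value_column)
    return MonthlyTimeSeries(start=YearMonth.from_index(int(idx[0])), values=full,
                             units=units, name=name)


def write_series_csv(ts: MonthlyTimeSeries, path: str | Path, float_format: str = "%.10g") -> None:
    ts.to_frame().to_csv(path, index=False, float_format=float_format)


def fill_missing(ts: MonthlyTimeSeries, method: str = "linear",
                 max_missing_fraction: float = 0.2) -> MonthlyTimeSeries:
    """Fill gaps so decomposition sees a gap-free series.

    ``linear`` interpolates in time (requires observed endpoints);
    ``seasonal_mean`` substitutes the mean of the same calendar month across
    years. Refuses when more than ``max_missing_fraction`` of entries are
    missing: interpolation artifacts would dominate the scale components.
    """
    miss = ts.missing
    if not miss.any():
        return ts
    frac = miss.mean()
    if frac >= max_missing_fraction:
        raise DataQualityError(
            f"{ts.name or 'series'}: {frac:.0%} missing exceeds the "
            f"{max_missing_fraction:.0%} fill limit")
    vals = ts.values.copy()
    if method == "linear":
        if miss[0] or miss[-1]:
            raise DataQualityError("linear fill needs observed first and last entries")
        t = ts.month_index()
        vals[miss] = np.interp(t[miss], t[~miss], vals[~miss])
    elif method == "seasonal_mean":
        cm = ts.calendar_months()
        for m in range(1, 13):
            sel = (cm == m) & miss
            if not sel.any():
                continue
            obs = (cm == m) & ~miss
            if not obs.any():
                raise DataQualityError(f"no observed values for calendar month {m}")
            vals[sel] = vals[obs].mean()
    else:
        raise ValueError(f"unknown fill method {method!r}")
    out = ts.with_values(vals)
    out.missing = np.zeros(len(ts), dtype=bool)
    return out


def season_subset(ts: MonthlyTimeSeries, window: CalendarWindow) -> dict[int, np.ndarray]:
    """Group values by year, keeping only months inside the window.

    For wrapping windows (e.g. Nov-Feb) a 'year' is the year of the window's
    first month, so one winter stays together. Missing entries are dropped.
    """
    out: dict[int, list[float]] = {}
    for i, ym in enumerate(ts.months()):
        if ts.missing[i] or not window.contains(ym.month):
            continue
        season_year = ym.year
        if window.wraps and ym.month <= window.last_month:
            season_year -= 1
        out.setdefault(season_year, []).append(ts.values[i])
    return {y: np.asarray(v) for y, v in sorted(out.items())}


def seasonal_yearly_means(ts: MonthlyTimeSeries, window: CalendarWindow) -> tuple[np.ndarray, np.ndarray]:
    """(years, mean value inside the window per year)."""
    groups = season_subset(ts, window)
    years = np.array(sorted(groups))
    means = np.array([groups[y].mean() for y in years])
    return years, means


# ---------------------------------------------------------------------------
# raster stacks


@dataclass
class RasterStack:
    """Monthly raster stack, indexed (time, row, col).

    ``transform``/``crs`` are carried through for provenance but no
    reprojection is ever performed (same-grid stacking only).
    """

    data: np.ndarray
    start: YearMonth
    nodata: np.ndarray | None = None
    transform: tuple[float, ...] | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("raster stack must be 3-D (time, row, col)")
        if self.nodata is None:
            self.nodata = ~np.isfinite(self.data)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.nodata.shape != self.data.shape:
            raise ValueError("nodata mask must match data shape")

    @property
    def n_months(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def months(self) -> list[YearMonth]:
        return [self.start.plus(i) for i in range(self.n_months)]

    def calendar_months(self) -> np.ndarray:
        m0 = self.start.month - 1
        return (m0 + np.arange(self.n_months)) % 12 + 1

    def window_mask(self, window: CalendarWindow) -> np.ndarray:
        cm = self.calendar_months()
        return np.array([window.contains(int(m)) for m in cm])

    def pixel_series(self, row: int, col: int) -> MonthlyTimeSeries:
        vals = self.data[:, row, col].copy()
        miss = self.nodata[:, row, col].copy()
        vals[miss] = np.nan
        return MonthlyTimeSeries(start=self.start, values=vals, missing=miss,
                                 name=f"pixel[{row},{col}]")


def read_raster_stack(path: str | Path, start: YearMonth | None = None) -> RasterStack:
    """Read a stack from multiband TIFF (one band per month) or NetCDF.

    TIFF georeference, start month and nodata sentinel are read from the JSON
    sidecar written by :func:`write_raster_stack` when present.
    """
    path = Path(path)
    if path.suffix in (".nc", ".cdf"):
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        var = [v for v in ds.data_vars if ds[v].ndim == 3][0]
        da = ds[var]
        t0 = pd.Timestamp(np.asarray(da["time"])[0])
        data = np.asarray(da, dtype=float)
        ds.close()
        return RasterStack(data=data, start=YearMonth(int(t0.year), int(t0.month)))
    import tifffile

    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    meta: dict = {}
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
    if start is None:
        start = YearMonth.parse(meta.get("start", "2001-01"))
    nodata_value = meta.get("nodata")
    nodata = None
    if nodata_value is not None:
        nodata = data == nodata_value
    return RasterStack(data=data, start=start, nodata=nodata,
                       transform=tuple(meta["transform"]) if meta.get("transform") else None,
                       crs=meta.get("crs"))


def write_raster_stack(stack: RasterStack, path: str | Path,
                       nodata_value: float = -9999.0) -> None:
    """Write a stack as multiband float32 TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    data = stack.data.astype(np.float32).copy()
    data[stack.nodata] = np.float32(nodata_value)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "start": str(stack.start),
        "nodata": nodata_value,
        "transform": list(stack.transform) if stack.transform else None,
        "crs": stack.crs,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def write_raster_map(arr: np.ndarray, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write one 2-D map (slope map, CV map, frequency map) as float32 TIFF."""
    import tifffile

    out = np.asarray(arr, dtype=np.float32).copy()
    out[~np.isfinite(out)] = np.float32(nodata_value)
    tifffile.imwrite(Path(path), out, photometric="minisblack")


def read_raster_map(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def stack_from_layers(layers: Sequence[np.ndarray], start: YearMonth) -> RasterStack:
    """Assemble same-shape 2-D layers (one per month, in time order)."""
    shapes = {np.asarray(l).shape for l in layers}
    if len(shapes) != 1:
        raise InputFormatError(f"layers have mixed shapes: {sorted(shapes)}")
    return RasterStack(data=np.stack([np.asarray(l, dtype=float) for l in layers]), start=start)
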