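"""End-to-end orchestration: synth -> decompose -> trends/CPA -> coupling -> report.

A run is fully described by a :class:`RunConfig` (YAML-round-trippable);
identical config + seed reproduces byte-identical outputs, which the run
report makes checkable by recording a checksum for every file written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (MonthlyTimeSeries, YearMonth, fill_missing, read_series_csv,
                   write_series_csv)
from .changepoint import detect_change_points
from .coupling import component_coupling, seasonal_curve
from .eemd import EEMDSettings, decompose_series
from .synthetic import default_coupled_config, gen_coupled_system, write_ground_truth
from .trends import cv_yearly, mann_kendall


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    #: paths per variable; empty means generate the demo synthetic system
    inputs: dict[str, str] = field(default_factory=dict)
    n_months: int = 240
    fill_method: str = "linear"
    ensemble_size: int = 100
    noise_amplitude_ratio: float = 0.2
    sift_count: int = 10
    noise_below: float = 6.0
    annual_upper: float = 24.0
    slope_threshold: float = 0.0005
    cpa_method: str = "binseg_trend"
    cpa_max_changepoints: int = 2
    cpa_min_segment_length: int = 12
    max_lag: int = 3
    max_accum: int = 3
    min_n: int = 24
    controls_mode: str = "joint"
    response_variables: tuple[str, ...] = ("level", "area")
    predictor_variables: tuple[str, ...] = ("ndvi", "temperature", "precipitation")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if out_dir is not None:
            raw["out_dir"] = out_dir
        raw.setdefault("out_dir", "run_out")
        cfg = cls(**raw)
        cfg.response_variables = tuple(cfg.response_variables)
        cfg.predictor_variables = tuple(cfg.predictor_variables)
        return cfg

    def _analysis_dict(self) -> dict:
        # out_dir is execution context, not an analysis parameter: two runs
        # of the same analysis into different directories must serialize and
        # hash identically
        d = asdict(self)
        d.pop("out_dir")
        d["response_variables"] = list(self.response_variables)
        d["predictor_variables"] = list(self.predictor_variables)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self._analysis_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self._analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)
    stages_completed: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


FLOAT_FMT = "%.10g"


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; any stage failure aborts with its name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), version=__version__)

    def record(path: Path) -> None:
        report.outputs[str(path.relative_to(out))] = _sha256(path)

    def write_df(df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        record(path)

    config.to_yaml(out / "config.yaml")
    record(out / "config.yaml")

    # ---- stage: load or synthesize -------------------------------------
    stage = "synth" if not config.inputs else "load"
    try:
        if config.inputs:
            series: dict[str, MonthlyTimeSeries] = {}
            for name, path in config.inputs.items():
                p = Path(path)
                if not p.exists():
                    raise FileNotFoundError(f"input for {name!r} not found: {p}")
                series[name] = fill_missing(read_series_csv(p, name=name),
                                            config.fill_method)
        else:
            synth_cfg = default_coupled_config(n_months=config.n_months,
                                               seed=config.seed)
            series, _ = gen_coupled_system(synth_cfg)
            write_ground_truth(synth_cfg, out / "ground_truth.json")
            record(out / "ground_truth.json")
            for name, ts in series.items():
                write_series_csv(ts, out / f"{name}.csv", FLOAT_FMT)
                record(out / f"{name}.csv")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e
    report.stages_completed.append(stage)

    # ---- stage: eemd ----------------------------------------------------
    try:
        settings = EEMDSettings(ensemble_size=config.ensemble_size,
                                noise_amplitude_ratio=config.noise_amplitude_ratio,
                                sift_count=config.sift_count, seed=config.seed)
        comps = {}
        period_rows = []
        for name, ts in series.items():
            d, sc = decompose_series(ts, settings, config.noise_below,
                                     config.annual_upper)
            comps[name] = sc
            report.warnings.extend(f"{name}: {w}" for w in d.ordering_warnings)
            for imf in d.imfs:
                period_rows.append({
                    "variable": name, "imf": imf.index,
                    "n_extrema": imf.n_extrema,
                    "mean_period_months": (np.nan if imf.mean_period is None
                                           else imf.mean_period),
                    "group": _group_of(imf.mean_period, config),
                })
                if imf.mean_period is None:
                    report.warnings.append(
                        f"{name}: imf{imf.index} has < 2 extrema, period undefined")
            comp_df = ts.to_frame()
            comp_df["c_noise"] = sc.c_noise
            comp_df["c_annual"] = sc.c_annual
            comp_df["c_interannual"] = sc.c_interannual
            write_df(comp_df, out / f"components_{name}.csv")
        write_df(pd.DataFrame(period_rows), out / "imf_periods.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("eemd", e) from e
    report.stages_completed.append("eemd")

    # ---- stage: trends + change points ---------------------------------
    try:
        trend_rows = []
        for name, ts in series.items():
            res = mann_kendall(ts)
            row = {"variable": name, "sen_slope_per_month": res.sen_slope,
                   "sen_slope_per_year": res.sen_slope_annual,
                   "mk_s": res.mk_s, "mk_z": res.mk_z, "mk_p": res.mk_p,
                   "n": res.n}
            try:
                row["cv_yearly"] = cv_yearly(ts).cv
                row["cv_class"] = cv_yearly(ts).class_label
            except Exception:
                row["cv_yearly"] = np.nan
                row["cv_class"] = ""
            trend_rows.append(row)
        write_df(pd.DataFrame(trend_rows), out / "trend_table.csv")

        cpa_out = {}
        for name in config.response_variables:
            if name not in series:
                continue
            r = detect_change_points(series[name], method=config.cpa_method,
                                     max_changepoints=config.cpa_max_changepoints,
                                     min_segment_length=config.cpa_min_segment_length)
            cpa_out[name] = {
                "method": r.method, "penalty": r.penalty,
                "breakpoints": r.breakpoints,
                "breakpoint_months": r.breakpoint_months,
                "segments": [{"start": s.start, "end": s.end,
                              "slope_per_month": s.slope,
                              "r_squared": s.r_squared} for s in r.segments],
            }
        (out / "changepoints.json").write_text(json.dumps(cpa_out, indent=1,
                                                          sort_keys=True))
        record(out / "changepoints.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("trends", e) from e
    report.stages_completed.append("trends")

    # ---- stage: coupling ------------------------------------------------
    try:
        rows = []
        preds = [p for p in config.predictor_variables if p in series]
        for component in ("annual", "interannual"):
            for resp in config.response_variables:
                if resp not in series:
                    continue
                grids = component_coupling(comps, component, resp, preds,
                                           max_lag=config.max_lag,
                                           max_accum=config.max_accum,
                                           min_n=config.min_n,
                                           controls_mode=config.controls_mode)
                for g in grids:
                    rows.append({"component": component, "response": resp,
                                 "predictor": g.predictor,
                                 "best_lag": g.best_lag,
                                 "best_accumulation": g.best_accum,
                                 "partial_r": g.best_r, "p_value": g.best_p,
                                 "n_effective": int(g.n_effective[g.best_lag,
                                                                 g.best_accum])})
        coupling_df = pd.DataFrame(rows)
        write_df(coupling_df, out / "coupling_table.csv")
        report.warnings.append(
            "coupling_table.csv: " +
            "best-cell p-values are selection-biased (max |r| over the grid)")

        season_rows = []
        for name, sc in comps.items():
            curve = seasonal_curve(sc.c_annual, series[name].start)
            for m in range(12):
                season_rows.append({"variable": name, "month": m + 1,
                                    "normalized_value": curve.values[m]})
        write_df(pd.DataFrame(season_rows), out / "seasonal_curves.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("coupling", e) from e
    report.stages_completed.append("coupling")

    report.to_json(out / "run_report.json")
    md = make_report(report, out)
    (out / "report.md").write_text(md)
    return report


def _group_of(T: float | None, config: RunConfig) -> str:
    if T is None or not np.isfinite(T) or T >= config.annual_upper:
        return "interannual"
    if T < config.noise_below:
        return "noise"
    return "annual"


def make_report(report: RunReport, out_dir: str | Path) -> str:
    """Render a run's result tables as markdown."""
    out = Path(out_dir)
    lines = [f"# hydroscale run report", "",
             f"- package version: {report.version}",
             f"- config hash: `{report.config_hash}`",
             f"- stages completed: {', '.join(report.stages_completed)}", ""]

    periods = out / "imf_periods.csv"
    if periods.exists():
        lines += ["## IMF mean periods and grouping", "",
                  _df_md(pd.read_csv(periods)), ""]
    cpa = out / "changepoints.json"
    if cpa.exists():
        lines.append("## Change points")
        data = json.loads(cpa.read_text())
        for var, res in data.items():
            lines.append("")
            if res["breakpoints"]:
                lines.append(f"**{var}** ({res['method']}): breaks at "
                             + ", ".join(res["breakpoint_months"]))
            else:
                lines.append(f"**{var}**: no change points at penalty "
                             f"{res['penalty']:.3g}")
            for s in res["segments"]:
                lines.append(f"- months [{s['start']}, {s['end']}): "
                             f"{s['slope_per_month']:+.4f}/month, "
                             f"R2 = {s['r_squared']:.2f}")
        lines.append("")
    trend = out / "trend_table.csv"
    if trend.exists():
        lines += ["## Trends and variability", "", _df_md(pd.read_csv(trend)), ""]
    coup = out / "coupling_table.csv"
    if coup.exists():
        lines += ["## Best lag/accumulation couplings", "",
                  _df_md(pd.read_csv(coup)), ""]
    if report.warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in report.warnings] + [""]
    return "\n".join(lines)


def _df_md(df: pd.DataFrame) -> str:
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in rec) + " |"
            for rec in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)
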