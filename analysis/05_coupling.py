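#!/usr/bin/env python
"""Lag/accumulation partial-correlation coupling at two timescales.

Normalized seasonal curves of the annual components, then the best
(lag, accumulation) partial correlation of lake level and area against
NDVI, temperature and precipitation for the annual and interannual
components — the per-timescale coupling tables. Compares recovered
lag/accumulation structure with the generator's coupling truth.
Outputs under results/coupling/.
"""

import json
from pathlib import Path

import pandas as pd

from hydroscale.core import read_series_csv
from hydroscale.coupling import component_coupling, seasonal_curve
from hydroscale.eemd import EEMDSettings, decompose_series

SEED = 42
BASE = Path(__file__).resolve().parent.parent / "results"
PREDICTORS = ["ndvi", "temperature", "precipitation"]


def main() -> None:
    out = BASE / "coupling"
    out.mkdir(parents=True, exist_ok=True)
    truth = json.loads((BASE / "data" / "ground_truth.json").read_text())

    settings = EEMDSettings(ensemble_size=100, noise_amplitude_ratio=0.2,
                            seed=SEED)
    series, comps = {}, {}
    for name in PREDICTORS + ["level", "area"]:
        ts = read_series_csv(BASE / "data" / f"{name}.csv", name=name)
        series[name] = ts
        comps[name] = decompose_series(ts, settings)[1]

    curves = []
    for name, sc in comps.items():
        c = seasonal_curve(sc.c_annual, series[name].start)
        curves.append({"variable": name,
                       **{f"m{m+1:02d}": c.values[m] for m in range(12)}})
        peak = int(c.values.argmax()) + 1
        print(f"{name:14s} seasonal peak in month {peak:2d}")
    pd.DataFrame(curves).to_csv(out / "seasonal_curves.csv", index=False,
                                float_format="%.5f")

    true_cpl = {c["driver"]: (c["lag"], c["accumulation"])
                for c in truth["variables"]["level"]["couplings"]}
    rows = []
    for component in ("annual", "interannual"):
        for response in ("level", "area"):
            for g in component_coupling(comps, component, response, PREDICTORS):
                rows.append({"component": component, "response": response,
                             "predictor": g.predictor, "lag": g.best_lag,
                             "accumulation": g.best_accum,
                             "partial_r": round(g.best_r, 3),
                             "p": g.best_p})
    table = pd.DataFrame(rows)
    table.to_csv(out / "coupling_table.csv", index=False, float_format="%.6g")
    print("\nbest lag/accumulation combinations "
          f"(generator truth for raw couplings: {true_cpl}):")
    print(table.to_string(index=False))
    print("\nnote: best-cell p-values are selection-biased "
          "(maximum |r| over the whole grid)")


if __name__ == "__main__":
    main()
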