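#!/usr/bin/env python
"""Generate the study system: coupled monthly series and demo rasters.

Writes a 20-year (240-month) coupled realization of temperature,
precipitation, NDVI, lake level and lake area — plus a trend/CV demo raster
and a binary water stack — under results/data/, with the generating ground
truth alongside as JSON.
"""

from pathlib import Path

import numpy as np

from hydroscale.core import write_raster_stack, write_series_csv
from hydroscale.synthetic import (default_coupled_config, gen_coupled_system,
                                  gen_trend_raster, gen_water_stack,
                                  write_ground_truth)

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_coupled_config(n_months=240, seed=SEED)
    series, _ = gen_coupled_system(cfg)
    for name, ts in series.items():
        write_series_csv(ts, OUT / f"{name}.csv")
    write_ground_truth(cfg, OUT / "ground_truth.json")
    print(f"coupled system: {len(series)} variables x {cfg.n_months} months "
          f"-> {OUT}")

    # raster with a north-south slope gradient and east-west CV gradient
    rows = cols = 12
    slope = np.linspace(-0.002, 0.002, rows)[:, None] * np.ones((1, cols)) / 12
    cv = np.ones((rows, 1)) * np.linspace(0.02, 0.3, cols)[None, :]
    stack = gen_trend_raster((rows, cols), slope, cv, n_months=240,
                             seed=SEED + 1, baseline=0.3)
    write_raster_stack(stack, OUT / "ndvi_stack.tif")
    np.savetxt(OUT / "raster_true_slopes.csv", slope, delimiter=",")
    print(f"trend raster: {rows}x{cols} pixels, 240 months")

    water, truth = gen_water_stack((20, 20), 240, permanent_fraction=0.85,
                                   fringe_occupancy=0.6, seed=SEED + 2)
    write_raster_stack(water, OUT / "water_stack.tif")
    print(f"water stack: {truth['wet_ever_pixels']} wet-ever pixels, "
          f"{truth['permanent_pixels']} permanent "
          f"(at-risk fraction {truth['at_risk_fraction']:.3f})")


if __name__ == "__main__":
    main()
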