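# hydroscale

Multi-timescale analysis of lake surface water, vegetation and climate from
monthly time series: scale decomposition by Ensemble Empirical Mode
Decomposition (EEMD), robust trend and change-point mapping, and
lag/accumulation partial-correlation coupling.

## The problem

In arid closed basins, lake level and area, vegetation greenness (NDVI) and
climate interact on several timescales at once: a seasonal cycle, multi-year
oscillations, and decadal trends with reversals. Correlating the raw monthly
series confounds these scales — a lake that responds to precipitation with a
3-month delay, and to vegetation through a 3-month cumulative water uptake,
shows almost no raw correlation with either. This package implements the
analysis chain that untangles such systems, for hydrologists and
remote-sensing ecologists working with monthly series and raster stacks:

1. **Scale decomposition.** A series x(t) is sifted into intrinsic mode
   functions (IMFs) and a residual, x(t) = Σ_j IMF_j(t) + r(t). EEMD
   decomposes an ensemble of noise-perturbed copies (ratio 0.2 of the input
   sd, 100 members by default) and averages the IMFs, suppressing mode
   mixing; the residual is defined by subtraction so the identity is exact.
   Each IMF gets a mean period T = 2L/n_extrema; IMFs are grouped into a
   noise component (T < 6 months), an annual component (6 ≤ T < 24) and an
   interannual component (T ≥ 24, plus the residual).
2. **Trends and variability.** Theil-Sen median slope with the Mann-Kendall
   test (tie-corrected variance, continuity-corrected z), per series or per
   pixel; slope classes improved / stable / degraded at ±0.0005 yr⁻¹;
   coefficient of variation CV = s/x̄ with a five-class volatility legend
   (0.05 / 0.10 / 0.15 / 0.20); growing-season vegetation masks (NDVI ≥ 0.1,
   March–October) and monthly water-frequency maps with the
   permanent/seasonal split.
3. **Regime segmentation.** Change points in lake level/area by PELT
   (Gaussian mean-shift cost, exact penalized optimum) or by exact
   dynamic-programming trend segmentation; each segment reported as an OLS
   rate (units/month) with R².
4. **Coupling.** Partial correlation of a response against predictor
   transforms over a (lag k, accumulation m) grid — the predictor summed
   over an m-month window ending k months earlier — controlling for the
   remaining drivers; the best combination (TL-k, TA-m) is estimated
   jointly across predictors by a backfitting sweep.

Because suitable real inputs (satellite water masks, altimetry lake levels,
NDVI composites) are large and access-restricted, the package ships a
first-class synthetic generator (`hydroscale.synthetic`) producing coupled
monthly systems and raster stacks with fully known ground truth — harmonics,
piecewise trends, AR(1) noise, lag/accumulation couplings — against which
every stage is validated.

## Worked example

```python
from hydroscale import default_coupled_config, gen_coupled_system
from hydroscale.eemd import EEMDSettings, decompose_series
from hydroscale.changepoint import detect_change_points
from hydroscale.coupling import joint_tl_ta_search

cfg = default_coupled_config(n_months=480, seed=7)     # 40 years, known truth
series, truth = gen_coupled_system(cfg)

d, sc = decompose_series(series["level"],
                         EEMDSettings(ensemble_size=100, seed=7))
print([round(i.mean_period, 1) for i in d.imfs if i.period_defined])
# [2.8, 7.4, 12.3, 35.6, 80.0, 240.0, 240.0]  <- noise | annual | interannual

cpa = detect_change_points(series["level"], method="binseg_trend",
                           max_changepoints=2)
print(cpa.breakpoint_months)               # ['2013-11', '2029-05']
grids = joint_tl_ta_search(cpa.detrended(series["level"]),
                           {q: series[q].values
                            for q in ("temperature", "precipitation", "ndvi")})
for name, g in sorted(grids.items()):
    print(f"{name:14s} TL-{g.best_lag}-TA-{g.best_accum}  r={g.best_r:+.2f}")
# ndvi           TL-0-TA-3  r=-0.72
# precipitation  TL-3-TA-0  r=+0.80
# temperature    TL-0-TA-0  r=+0.91
```

The decomposition places an IMF at the 12-month seasonal cycle and slower
IMFs in the interannual group. The generator planted trend breaks at months
160 and 320 (2014-05 and 2027-09): segmentation lands within six months of
the sharp decline→stable kink and within the ~2-year localization limit of
the much subtler stable→rise kink (a slope kink without a level jump is
localizable only to ~(σ²/Δslope²)^⅓ months). The joint grid search recovers
the generating couplings exactly — precipitation acts with a 3-month lag,
NDVI through a 3-month accumulation with negative sign, temperature
synchronously — the statistical fingerprint this kind of watershed analysis
looks for.

The same pipeline runs end-to-end from a shell:

```bash
hydroscale run --out runs/demo --seed 7 --n-months 240
hydroscale eemd --in runs/demo/level.csv --seed 7 --out runs/demo_eemd
hydroscale cpa --in runs/demo/level.csv --max-cp 2 --method binseg_trend --out cpa.json
```

The numbered scripts under `analysis/` execute the full study narrative
(simulate → decompose → trends/maps → change points → coupling) and write
their tables under `results/`.

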