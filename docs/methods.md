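# Methods

This note documents the models and procedures implemented in `hydroscale`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model

The atomic time unit is the calendar month. A `MonthlyTimeSeries` stores a
contiguous monthly index from a start month; record gaps are explicit mask
entries, never omitted rows, so every statistic sees the true time axis.
Decomposition and segmentation require gap-free input; `fill_missing`
provides linear interpolation (default) or same-calendar-month means, and
refuses when ≥ 20% of entries are missing, since interpolation artifacts at
that density would leak into the annual component. Raster stacks are
(time, row, col) arrays with a per-cell nodata mask; pixels missing in more
than 10% of time steps are excluded from per-pixel statistics. Raster I/O is
multiband float32 TIFF with a JSON sidecar carrying the start month,
nodata sentinel and georeference, plus NetCDF3 via xarray; no resampling or
reprojection is performed — stacking assumes one shared grid.

## EEMD and scale components

Plain EMD extracts IMFs by sifting: cubic-spline envelopes through the
interior maxima and minima, subtract the envelope mean, repeat. Choices:

- **Extrema.** Strict interior extrema; a plateau counts once, at its
  midpoint. Endpoints are never extrema.
- **Boundaries.** The two extrema nearest each end are mirrored across the
  series boundary before spline fitting, the standard guard against
  envelope divergence. With fewer than four knots the envelope falls back
  to linear interpolation.
- **Stopping.** A fixed sift count (default 10) per IMF instead of an
  SD-threshold: deterministic, and it keeps IMF counts aligned across
  ensemble members. Extraction stops when the running residual has fewer
  than two interior extrema, or at `max_imfs` (default ⌊log₂ n⌋ − 1).
- **Conservation.** Each IMF is subtracted from the running residual, so
  input = Σ IMFs + residual holds to floating-point rounding (~1e-14).

EEMD decomposes `ensemble_size` (default 100) copies of the input with
added white noise of sd `noise_amplitude_ratio` (default 0.2) × sd(input),
averages IMFs position-wise with a common fixed IMF count, and defines the
residual by subtraction so the additive identity stays exact. Noise ratio 0
short-circuits to plain EMD, bit for bit. Ensemble averaging can perturb
the strict fast-to-slow ordering of mean periods; a single inversion is
recorded as a note, more than one raises a warning.

**Mean period.** T = 2L / n_extrema, with n_extrema the interior maxima
plus minima over the record of L months. The extrema count over twice the
record length is a frequency; the period is its reciprocal, and the formula
is exact for sinusoids (a P-month tone over L months has 2L/P extrema).
Both the count and T are reported; an IMF with fewer than two extrema has
an undefined period and is treated as trend-like.

**Grouping.** T < 6 months → noise component; 6 ≤ T < 24 → annual;
T ≥ 24, undefined-period IMFs and the residual → interannual. The cutoffs
are configurable; the half-open convention at 6 and 24 makes the three
components an exact partition of the reconstruction.

## Trends, variability, water frequency

- **Theil-Sen**: median of all pairwise slopes over month indices (missing
  entries keep their calendar position); annualized = 12 × monthly.
- **Mann-Kendall**: S = Σ sign differences; Var(S) with the tie-group
  correction [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18; z with ±1 continuity
  correction; two-sided normal p. P-values are reported raw — no
  multiple-testing correction across pixels.
- **Slope classes**: improved (≥ +0.0005 units/yr), degraded (< −0.0005),
  stable otherwise; at exactly +0.0005 the improved class wins.
- **CV**: sample (n−1) standard deviation over the mean, computed by
  default on yearly growing-season means (interannual variability); class
  bounds 0.05 / 0.10 / 0.15 / 0.20, lower bound inclusive.
- **Vegetation mask**: growing-season (March–October) mean NDVI ≥ 0.1,
  inclusive, either in every observed year (default) or on the
  across-years mean. The threshold comparison carries 1e-12 absolute slack
  so that averaging exactly-threshold samples cannot fall below it by one
  ulp.
- **Water frequency**: percent of valid in-window months a pixel is water;
  permanent ⇔ 100%; the at-risk fraction is the share of wet-ever pixels
  that are not permanent.

## Change-point segmentation

Two detectors over a gap-free monthly series, both deterministic:

- `pelt_mean`: exact penalized optimal partitioning (PELT pruning) under a
  Gaussian mean-shift cost — segment SSE normalized by a robust noise
  variance estimated from first differences (MAD-based; differencing keeps
  slow trends from inflating the estimate). Penalty presets: numeric,
  `bic` = 2 log n, `mbic` = 3 log n (default) in those normalized units.
- `binseg_trend`: exact dynamic-programming minimization of the total RSS
  of per-segment OLS lines. An explicit `max_changepoints` is the requested
  break count; without one, the break count (≤ 3) is chosen by
  penalization. DP is used instead of greedy splitting because gradual
  slope changes displace greedy split points.

`min_segment_length` defaults to 12 months — lake regimes of interest span
years, and the floor keeps sub-annual wiggles from fragmenting the series.
Breakpoints are reported as calendar months via the series start. Segments
are summarized by OLS slope, intercept and R².

A localization caveat that shapes the tests: a slope change **without** a
level jump carries information that grows only cubically with distance from
the kink, so the break location error scales like (σ²/Δslope²)^⅓. A
decline→stable kink of 0.06 units/month is localizable to ±3 months only
when noise is a few percent of the series range; a 0.005 units/month kink
is localizable only to a ±2-year window even then. Mean *steps* (used in the
step-recovery validation) do not suffer this and are found exactly.

## Lag/accumulation partial-correlation coupling

The predictor transform TA-m/TL-k is the rolling **sum** over an m-month
window ending k months earlier (correlation is scale-invariant, so sum
versus mean is immaterial; sum matches the "k-month cumulative" reading).
TA-0 and TA-1 are operationally identical (a one-month window); grids
report both cells and ties resolve toward the smaller index, then the
smaller lag. Grid bounds default to lag, accumulation ≤ 3 months.

Partial correlation is computed by OLS residualization of both variables on
the controls (intercept included); p from t = r√(df/(1−r²)), df = n − 2 −
#controls, two-sided. Residuals below 1e-10 of the variable's scale mark an
affine dependence on the controls and the correlation is flagged undefined.

**Joint estimation.** When drivers share seasonal phase, a grid search with
untransformed controls misattributes their overlap, and transforming each
control only against the response is not much better. The default is
therefore a backfitting scheme: every predictor's best (lag, accumulation)
is estimated with the other predictors controlled at their current best
transforms, sweeping the predictor set twice (one initial pass with raw
controls, one refinement). On the reference synthetic system this recovers
all three generating combinations in ≈ 99% of realizations, where
single-pass variants recover under half.

**Selection bias.** The best cell maximizes |r| over the grid, so its
p-value is optimistic; every grid object and every written table carries an
explicit selection-bias note. Serial correlation additionally inflates the
parametric test (the effective sample size is below n); the permutation
test in the suite therefore prewhitens monthly anomalies before comparing
rejection rates with the nominal level.

**Timescale-resolved tables.** `component_coupling` runs the search on the
annual or interannual components of all variables. Narrowband annual
components carry an intrinsic phase ambiguity — any lag of a pure tone is a
linear combination of the tone and its quadrature — so lag estimates from
annual components are less stable than from the broadband detrended series,
and sign estimates for weakly coupled drivers can flip in some
realizations. The ground-truth recovery validation therefore runs on the
change-point-detrended raw series, which is also the recommended practice.

**Seasonal curves.** Calendar-month means of the annual component across
years, normalized by the sum of absolute month means (Σ|values| = 1), so
variables of different units and amplitudes are comparable.

## Synthetic generator

`gen_coupled_system` produces temperature, precipitation, NDVI, lake level
and lake area with exactly known structure: per-variable harmonics
(seasonal + multi-year), continuous piecewise-linear trends, stationary
AR(1) noise (marginal sd as specified), and linear-additive couplings
(coefficient × accumulated-then-lagged driver). Responses are generated
with a 24-month burn-in so every output month has a complete window, making
noiseless couplings exact identities. The same seed gives bit-identical
output, per variable, regardless of call order.

The reference configuration emulates an arid mid-latitude watershed on a
2001-anchored monthly axis:

| variable | seasonal amplitude | multi-year | AR(1) sd | φ |
|---|---|---|---|---|
| temperature | 15 °C, July peak | 0.8 °C / 60 mo | 2.0 °C | 0.3 |
| precipitation | 12 mm, June peak | 3 mm / 60 mo | 8 mm | 0.2 |
| NDVI | 0.12, July peak | 0.02 / 60 mo | 0.03 | 0.3 |

Lake level couples to temperature synchronously (+0.05 m/°C), to
precipitation with a 3-month lag (+0.02 m/mm) and to 3-month-accumulated
NDVI negatively (−1.2 m per unit); area uses the same structure at its own
scale. The coefficient hierarchy (temperature strongest positive,
precipitation intermediate, NDVI weakest negative) mirrors the ordering of
coupling strengths such watershed studies report, and keeps the lake's
seasonal cycle in phase with temperature as observed in snow/glacier-fed
basins. Both lake variables carry a decline/stable/recovery piecewise trend
(breaks at ⅓ and ⅔ of the record) and AR(1) noise whose sd is 0.3 × the
realized coupling-signal sd — the study condition for all recovery
experiments. Precipitation is Gaussian and can dip below zero in winter
months; the generator reproduces the second-order statistics the analysis
consumes, not physical non-negativity, skewness, or any process hydrology
(no snowmelt, runoff routing or human abstraction). Passing the recovery
tests therefore demonstrates correctness of the estimators under linear
couplings with AR(1) disturbances, not robustness to every property of real
records.

`gen_trend_raster` builds per-pixel series `baseline + slope·(t − t̄) +
white noise`, solving the noise sd from a target CV after subtracting the
trend's own variance contribution. `gen_water_stack` builds a centered
wet-ever rectangle whose innermost `round(p · wet_ever)` pixels (Chebyshev
distance, stable ties) are permanently wet; fringe pixels are wet
independently per month at the given occupancy, forced to at least one wet
and one dry month so "permanent ⇔ 100% frequency" and the at-risk fraction
are exact by construction.

## Problem sizes and determinism

Validation experiments use n = 240 months for conservation/step-recovery
experiments (a two-decade record) and n = 480 for coupling recovery (the
joint grid search benefits from a longer record), with 100–200 Monte-Carlo
repetitions and 2000 null simulations for test calibration; these sizes
make all headline rates stable to a few percent across seeds. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline writes every output with a fixed
float format and records a sha256 per file, and two runs with the same
config and seed are byte-identical (the output directory itself is
execution context and excluded from the config hash).

## Known limitations

- EMD/EEMD here is the classical formulation: no CEEMDAN-style adaptive
  noise, no significance test of IMFs against a white-noise spectrum.
- Mean-period estimation by extrema counting is coarse for weak or mixed
  modes; periods are reported alongside extrema counts so users can judge.
- The parametric p-values in both Mann-Kendall (per pixel) and the coupling
  grids ignore spatial and serial correlation respectively; the package
  flags, but does not correct, the resulting optimism.
- Lag/accumulation estimates from narrowband components are phase-ambiguous
  (see above); prefer the detrended broadband series for lag inference.
- Change points are located without confidence intervals, and slope-kink
  localization is physically limited as described.
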