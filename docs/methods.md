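# Methods

This note records the modelling assumptions, default parameters, numerical
choices and known limitations of the package. Everything quantitative
stated here is computed by the test suite or the acceptance script; nothing
is asserted from memory.

## The disparity index

YLL for one death is the remaining life expectancy at the completed age and
sex of death, looked up in a single-year life table without interpolation.
Daily totals are stratified by terciles of an area-level deprivation
indicator (% of adults without a high-school diploma, in [0, 100]; higher =
more deprived = more vulnerable). Tercile cuts are the type-1
(inverse-empirical-CDF) 1/3 and 2/3 quantiles of the indicator over all
deaths in the study period — deaths-weighted, not area-weighted — computed
once and applied throughout; values equal to a cut go to the
lower-vulnerability side. The index for day *d* is the mean excess of the
non-reference terciles over the most advantaged (reference) tercile.
Negative days (reference group worse off) are preserved in the series;
how to handle them is a modelling decision, not an indexing one.

A consequence of deaths-weighted cuts worth knowing: each labelled tercile
contains one third of all deaths by construction, so the *baseline* (cool
day) expected disparity is approximately zero and the long-run mean DYLLD
is driven by the heat effect. Observed-data analyses that build terciles
from area units instead typically show a large positive baseline disparity
because deprived areas also have higher everyday mortality; with
deaths-weighted cuts that baseline gap is absorbed by construction. The
choice is configurable in spirit (cuts can be passed explicitly to
`assign_terciles`) but deaths-weighted is the default.

## Exposure-response model

The daily index is related to same-day (lag 0) mean temperature by a GLM:

- **Family.** Quasi-Poisson with log link, treating DYLLD (years) as a
  nonnegative intensity. Negative days are floored at zero by default and
  the floored fraction is recorded in the fit's warnings; with
  deaths-weighted terciles roughly half of the cool-season days are
  floored, which raises the model's baseline above zero and means the
  attributable estimand lives on the floored scale (the truth-recovery
  test's oracle is computed on that same scale). A Gaussian identity-link
  alternative is provided for sensitivity, with RR defined as
  predicted/period-mean.
- **Adjustments.** Natural cubic spline of day-of-summer (default 3 df),
  a linear between-year trend (a year-factor option exists), and linear
  daily relative humidity. The spline basis is patsy's `cr`; because that
  basis is a partition of unity, one extra column is requested and dropped
  so the design stays full rank next to the explicit intercept.
- **Dispersion.** Pearson X² estimate; the coefficient covariance is the
  IRLS covariance scaled by it. An independent hand-written IRLS loop in
  the test suite reproduces coefficients and covariance to 6 significant
  figures.
- **Threshold.** Hockey-stick term (T − τ)+ with τ searched on a 1 °C grid
  from ⌈50th percentile⌉ to the 98th percentile of observed temperature.
  Candidates whose deviance lies within χ²₁(0.95) × dispersion of the
  minimum form a profile confidence set for τ; the **median member** of
  that set is selected. Selecting the raw deviance minimiser is biased
  toward extreme slopes when the profile is flat — under a designed null
  (no heat effect) the naive 95% slope CI covered zero in only ~87% of
  simulations, versus ~94–95% with the median rule, while recovery of a
  designed 23 °C threshold within ±1 °C remained at ~86–98% across
  simulation scales. Candidates that fail to converge are recorded in the
  deviance profile and skipped; if all fail, a model error with the full
  profile is raised. Fewer than 10 days above the selected threshold
  triggers a recorded warning.

## Attributable burden

Two modes, both per 100,000 persons per summer:

- **observed-dylld** (historical analyses): Σ over days with T > τ of
  DYLLD_d × (RR(T_d) − 1)/RR(T_d) — the attributable-fraction form applied
  to the observed series.
- **constant-baseline** (projections): Σ of mean(DYLLD) × (RR(T_d) − 1) —
  requires no future disparity observations, so the ICC ratio is
  well-defined.

Standard errors come from 1,000 seeded multivariate-normal draws of the
coefficient vector (SVD factorisation of the covariance), with percentile
95% intervals. These intervals carry *coefficient* uncertainty only: they
exclude day-to-day sampling noise of observed DYLLD and threshold-selection
uncertainty, so they should be read as curve uncertainty, not full
predictive uncertainty. The truth-recovery test therefore checks
unbiasedness of the estimator averaged across simulation replicates rather
than per-replicate CI coverage.

## Climate projection

Scenario series are bias-corrected by empirical quantile–quantile mapping
calibrated on the scenario's historical period against observed summer
temperatures: linear interpolation between order statistics, endpoint-offset
extrapolation beyond the calibration range, all summer days pooled (no
per-month mapping). The mapping is exactly monotone and satisfies the
calibration identity, identity transfer, and shift-invariance properties to
interpolation tolerance.

The impact of climate change (ICC) per scenario is the ratio of future
(default 30 summers) to historical (30 summers) constant-baseline
attributable rates, using the same fitted curve and population for both
periods — the no-acclimatisation, no-demographic-change assumption.
Population and baseline DYLLD cancel algebraically in the ratio (asserted
numerically to 1e-9). Numerator and denominator share the same coefficient
draws, so the log-ICC standard error retains their correlation. Scenarios
with a zero historical rate are flagged and excluded from pooling.

## Meta-analysis

DerSimonian–Laird random-effects pooling: method-of-moments τ² floored at
zero, weights 1/(SE² + τ²), normal-theory 95% intervals (z = 1.96). Ratios
(ICC) are pooled on the log scale and exponentiated; the reporting-scale SE
uses the delta method. Pooled estimates are compared by a Welch-style z
test. Meta-regression on a binary city indicator uses the method-of-moments
residual τ² (Q_E − (k − p)) / tr(P) and weighted least squares; ICC
meta-regression is run on the identity scale (an interpretable ICC
difference), future rates on the ln scale, and both scales are reported by
the pipeline. Expected values for the pooling and meta-regression tests
were frozen from an independent reference implementation of the same
estimators. REML is not implemented; with 30-member ensembles and moderate
heterogeneity the method-of-moments estimator is adequate and exactly
reproducible.

## Synthetic-data generator

The generator defines the study conditions for every test:

- **Weather.** Daily summer (June–August) mean temperature = seasonal
  sinusoid peaking July 15 (default amplitude 2 °C, centred over the
  generated days) + stationary AR(1) noise (default ρ = 0.6). The noise SD
  is √max(0, σ² − var(seasonal)) so the series SD matches the configured
  σ (default 3.24 °C around a 20.4 °C mean); with σ = 0 the series is
  exactly the deterministic seasonal mean. Humidity is i.i.d. Gaussian
  truncated to [0, 100] (default 65 ± 12%).
- **Deaths.** Daily counts per tercile are Poisson with mean
  baseline × p_j × exp(β_j · (T − τ)+); defaults: 37 deaths/day (≈3,400
  per summer), equal tercile probabilities, τ = 23 °C, and β =
  (0.09, 0.05, 0.02) per °C for the (low, mid, high)-SES terciles — the
  designed vulnerability gradient. The heat effect is placed on counts,
  not on DYLLD directly, so the index's response emerges through
  aggregation as it would in real data. Ages are truncated-Gaussian
  (mean 78, SD 12, range [35, 105]) completed years; sexes are equally
  likely; the SES indicator is uniform within the tercile's fixed band
  ([0, 33.3), [33.3, 66.7), [66.7, 100]).
- **Life table.** Gompertz mortality (a = 3e-5, c = 0.09/year) integrated
  numerically (trapezoid, 0.05-year grid) to remaining life expectancy per
  completed age; female values add a 4-year gap at birth, tapering linearly
  so both schedules stay strictly decreasing. Mean YLL per generated death
  is ~14 years.
- **Scenario ensemble.** Default 30 scenarios; each has an additive bias
  ~ N(0, 1 °C) (exercising the quantile mapping) and an independent future
  draw shifted further by a warming delta ~ N(1.35, 0.3²) °C over 30-summer
  periods.
- **Reproducibility.** Each output type uses its own RNG stream derived
  from the master seed with a fixed stream id, so e.g. enlarging the
  ensemble never perturbs the death series; identical (config, seed) give
  byte-identical outputs.

What the generator does **not** emulate: geographic structure (no areas or
maps — the SES indicator is attached directly to deaths), multi-day
heat-wave episodes and lagged effects, mortality displacement, demographic
change across years, cause-of-death structure, and the baseline mortality
gradient across deprivation groups discussed above. Passing tests therefore
demonstrate correctness of the estimators under a clean data-generating
process with the designed effect structure, not robustness to those
real-data features.

One scale consequence: with ~37 deaths/day and remaining-life-expectancy
YLL (~14 years/death), simulated daily YLL totals are ~500 years — real
cities of this size report daily YLL several times larger, consistent with
YLL constructions closer to full life expectancy at birth per death. The
two anchors (deaths per summer and daily YLL level) cannot both be matched
under the standard YLL construction; the generator anchors death counts,
which drive the statistical behaviour of every estimator.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use 18 summers × 92 days at ~37 deaths/day for
parameter-recovery and calibration properties (50–100 seeds), 6–10 summers
for fixtures and the demo pipeline, and 30-scenario × 30-summer ensembles
in the acceptance script. These sizes were chosen to make the Monte-Carlo
bands in the tests tight at, roughly, the scale of the emulated studies.

## Known limitations

- Lag 0 only; no distributed-lag structure.
- The hockey-stick RR is log-linear above the threshold; true saturating or
  accelerating shapes are approximated, and under flooring the fitted RR is
  a log-linear approximation to a not-exactly-exponential mean ratio.
- Coefficient-draw SEs understate full predictive uncertainty (see above).
- The quantile mapping assumes the scenario's historical-period bias is
  stationary into the future period.
- Meta-regression treats per-scenario SEs as known, as is conventional.
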