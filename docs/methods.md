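# Methods

This note documents the models and procedures implemented in
`droughtlegacy`, the choices made where the design was genuinely open, and
what the synthetic experiments do and do not demonstrate.

## Problem

After a severe drought, ecosystem functioning (carbon uptake, transpiration)
may remain suppressed even once meteorological conditions have returned to
normal — a *legacy effect*. Detecting one requires an estimate of what the
fluxes *would* have been given the observed post-drought meteorology. The
package implements a residual approach: a machine-learning model of the
flux–meteorology relation is trained on years outside the post-drought
period, predicts the post-drought period from its observed drivers, and the
residual (observed − predicted) is tested against an uncertainty envelope
derived by leave-one-year-out cross-validation.

## Synthetic scenario generator (`scenario`)

The generator emulates the statistical structure of a Mediterranean
evergreen-oak flux site with a two-decade daily record, a severe
late-season drought year, and a record-wet first post-drought year. It is
first-class, tested code: every acceptance experiment runs on its output.

* **Calendar.** 365-day years (leap days dropped) so day-of-year and the
  7-day week grid align exactly across years; the 52nd week spans 8 days.
* **Drivers.** Air temperature, shortwave radiation, VPD and wind speed are
  annual harmonics plus stationary AR(1) anomalies (`scipy.signal.lfilter`).
  Precipitation is an occurrence × amount process: wet-day probability peaks
  in winter with a July minimum, wet-day amounts peak in the autumn storm
  season; expected annual total ≈ 950–1050 mm. Soil water content is a
  single-bucket balance (capacity 400 mm, standing in for a deep rooting
  zone in rocky soil): gain from precipitation, loss proportional to a
  VPD·temperature demand limited by the current store, clipped to [0, 1] as
  a fraction of capacity. Every summer draws the bucket down — this matters
  for the detector, because it places ordinary years across the low-soil-
  water response range so that the drought year is not a unique
  extrapolation.
* **Drought and wet year.** The drought year scales wet-day amounts by
  (1 − 0.89) in July–September (leaving ~11% of climatology) and by
  (1 − 0.23) in the remaining months, reproducing the year-round dryness of
  an observed severe drought year (annual total ≈ 65% of climatology). The
  first post-drought year receives a +55% precipitation surplus.
* **Fluxes.** GPP, ET and sap flow are products of four driver kernels —
  saturating in radiation, Gaussian in temperature, linear-below-threshold
  in soil water, hyperbolically decreasing in VPD — with flux-specific
  coefficients, additive Gaussian noise truncated at zero, and (for sap
  flow) small lognormal per-tree factors. The true flux–driver forms are a
  modelling choice; any shapes of comparable predictability would serve,
  since the detector learns the relation nonparametrically. Noise levels
  are set so a random forest reaches an out-of-bag pseudo-R² near 0.9,
  matching the skill regime the method operates in on real flux data.
* **Legacy effect.** An optional multiplicative suppression
  `1 − λ·exp(−(t − onset)/τ)` applies to all fluxes from the onset (default
  1 January of the first post-drought year). λ = 0 is the null scenario.
  The multiplier is applied after noise, so null and alternative scenarios
  with the same seed share every random draw and differ only from the onset
  on — exact coupled counterfactuals for power experiments.
* **Sensors.** Each tree carries several sap-flow sensors whose gain decays
  exponentially (probe detachment by stem growth) and resets to 1 at
  replacement dates; records get isolated gaps, multi-week outage blocks,
  and rare spikes several annual SDs from the annual mean. A half-hourly
  mode expands daily values into a seasonal-daylength half-sine diurnal
  course whose daytime mean equals the daily value exactly.

What the generator does **not** emulate: physically mechanistic soil or
plant hydraulics, energy balance, phenology, co-variation between VPD and
precipitation occurrence, instrument-era shifts in the EC record, or
spatially heterogeneous tree responses. Passing tests therefore show the
*method* behaves correctly under realistic statistical structure, not that
any particular field result is reproduced.

## Sap-flow processing (`sapflow`)

Four fixed-order steps, a–c per sensor, d per tree; no gap-filling anywhere
(steps a–c never create values on days that had none; step d only fills a
day when at least one sensor reports):

a. **Aggregate and filter.** Daytime mean of half-hourly values; a day needs
   ≥ 70% of its daytime slots (inclusive — "at least" thresholds are read as
   ≥). Years with < 40% daily coverage are dropped entirely. A single pass
   per calendar year removes values more than 3 sample SDs from the annual
   mean (no iterative re-estimation; the removal is a sub-1% effect under
   default noise, so a second pass would be inconsequential).
b. **Long-term trend removal.** STL (`statsmodels`) with annual period and a
   3-year (1095-day) loess trend window on a linearly interpolated working
   copy; the trend is subtracted from the original, gaps stay gaps.
c. **Variance normalization.** Each calendar year is divided by the sample
   SD of the detrended values in a 3-year moving window. The window is
   centred (year ± 1) by default and truncated at record edges (2 years);
   a trailing alignment is available as a configuration switch since the
   centring convention is not canonical.
d. **Tree mean.** Per-day mean across sensors with a value, with the
   contributing-sensor count recorded.

Numerical guards: a window SD below 1e-8 aborts with a diagnostic
(near-constant signal); detrending refuses records with fewer than 3 years
of retained data; years with fewer than two valid days skip outlier
filtering.

## Flux normalization (`fluxnorm`)

* **Segment z-scoring.** Eddy-covariance instrument eras (default break at
  2014-01-01) are z-scored independently with the sample SD and
  concatenated; idempotent and rank-preserving within segments. Each
  segment must hold ≥ 30 valid days and nonzero variance.
* **WUE.** GPP/ET is formed on the physical scale *before* any z-scoring (a
  ratio of z-scores has no meaning), then treated like any other flux. Days
  with ET below a floor — default the 1st percentile of positive ET — are
  set missing rather than producing ratio blow-ups; the floored count is
  reported.
* **Greenness detrending.** Satellite greenness is corrected by OLS on time
  (residuals plus the overall mean, preserving the level), with the slope
  and its t-statistic reported.

Note for synthetic experiments: the generator produces no instrument shift,
so the detection experiments use the flux series directly (a single global
z-score would be equivalent up to scale). Applying a two-era z-score to a
shift-free series slightly distorts the cross-era relation — the segment
means differ by climate sampling alone, e.g. the drought sitting in one
era — and that distortion would register as a spurious one-sided residual
signal.

## Legacy detection (`legacy`)

* **Model.** `RandomForestRegressor` with the R `randomForest` regression
  defaults the method was established with: 500 trees (experiment configs
  use fewer — see below), mtry = ⌊p/3⌋, node size 5, bootstrap resampling,
  out-of-bag pseudo-R² recorded. Predictors: SWC, VPD, SW_IN, TA, WS,
  precip; optionally month-of-year; for the pooled sap-flow model the tree
  identity enters as a one-hot categorical with a fixed sorted level set.
  Predictions are invariant to tree-label permutation up to forest
  randomness (exact bit-level invariance is impossible because the one-hot
  column order seeds different split sequences); the test asserts
  statistical agreement.
* **Training mask.** The post-drought years (and any explicitly predicted
  years, e.g. the drought year in the predictability variant) are excluded
  from every fit; the exclusion is asserted programmatically inside
  `fit_predict`, so a leak raises rather than silently biasing results.
  Missing predictor or target days are dropped, never imputed.
* **Uncertainty.** For each non-post-drought year, a forest trained without
  it (and without the post-drought years) predicts it; daily residuals are
  averaged to weekly means; per week-of-year, the 5/25/75/95 percentiles
  across held-out years form the envelope. Weekly-mean residuals and a
  per-week envelope are the defaults because flagging is weekly and model
  uncertainty is strongly seasonal; pooled-global and daily-residual
  variants are configuration switches. The mean over years of the daily
  residual RMSE is reported as the leave-one-out RMSE.
* **Flagging.** A post-drought weekly residual strictly above p95 (below
  p5) is flagged positive (negative); boundary values are not flagged;
  weeks without residual days are reported missing.
* **Pooled sap flow.** The pooled model's per-tree residuals are averaged
  per day before weekly aggregation, giving ecosystem-scale flags.

### Calibration properties (what the experiments show)

With 17 contributing years, empirical 5th/95th percentiles are
small-sample-noisy: the expected fraction of exchangeable new weekly
residuals falling outside the envelope is close to 0.17–0.20 rather than
the nominal 0.10 (the k-th order statistic of n samples is exceeded with
probability ≈ k/(n+1)). The null-calibration acceptance test therefore
checks the flagged fraction against the designed range [0.03, 0.22] rather
than the nominal rate. A small positive-flag excess (~0.03 absolute) is
expected and physically interpretable: the record-wet first post-drought
year pushes the drivers mildly outside the training envelope, and a forest
cannot extrapolate, so observed fluxes slightly exceed predictions; the
symmetry check allows a difference of up to 0.06 between the mean positive
and negative flag rates, about a third of the total null rate.

Monte-Carlo experiment sizes: 20 scenario replicates per condition with
50-tree forests in the test suite (the envelope percentiles and flag rates
are insensitive to forest size well below the 500-tree default, which
matters for point-prediction variance, not for rank-based envelopes);
8 replicates in the acceptance script. The skill checks use 200 trees.

## Impact statistics (`impact`)

* Period means (full year, halves split at 1 July) for a focal year are
  compared with all other years: SD-scaled anomaly
  (focal − mean others)/SD(others), and the rank fraction of years (focal
  included) with a period mean ≤ the focal one — ties count toward the
  focal rank, and identical reference years with a differing focal value
  yield a signed infinite anomaly rather than an error.
* Record-extreme runs: a day-of-year is a pointwise extreme only if the
  focal year is *strictly* beyond every other year (ties conservatively
  yield none; days with any missing year are skipped); maximal runs longer
  than one week (≥ 8 days) are reported.
* The moving-average smoother is presentation-only and deliberately kept
  out of every statistical path.

## Known limitations

* The envelope is a finite-sample percentile band, not a predictive
  interval; with ~17 reference years its nominal 90% coverage is closer to
  80–83%, and all detection rates should be read against the null rate the
  same pipeline produces.
* Suppressions much shorter than a month or weaker than ~10% are below the
  envelope's resolution at this record length.
* Segment z-scoring assumes the instrument change is the only cross-era
  inconsistency; climate sampling differences between eras leak into the
  normalized scale (see above).
* The sap-flow chain recovers *dynamics*, not physical sap-flux density;
  absolute processed values are uninterpretable by construction.
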