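# Methods

## Design

The package analyses a quasi-experimental interrupted time series: a
monthly binomial outcome (the proportion of eligible patients starting,
or of ending prescription episodes not renewed) observed over a study
window of 51 calendar months, with a 6-month exposure window (October
2013 – March 2014 by default) treated as a potential interruption.
Time is segmented into before / during / after, and the post-exposure
level and slope are estimated against the pre-exposure trajectory.

## Cohort construction

**Episodes.** A prescription of `quantity` tablets at `daily_dose`
tablets/day covers `ceil(quantity / daily_dose)` days from its issue
date. A missing dose falls back to the per-drug median dose computed
over the input table; records with no computable duration are dropped
and counted in the log.

**Cessation.** The unit of analysis is an episode whose computed end
date falls in a calendar month; a patient contributes one unit per
qualifying episode. The outcome is "no further prescription issued
within 28 days of the end date", with inclusive day counting: a next
issue on day 28 is a continuation, day 29 a cessation. The denominator
requires the patient to be over 40 (exact age from a mid-year date of
birth, since only the birth year is recorded), and to remain alive and
under follow-up through the full grace window; in the primary-prevention
series a first cardiovascular event on the end date or inside the
window also removes the episode. Episodes are classified primary or
secondary by whether a cardiovascular event strictly precedes the end
date. Overlapping prescriptions are not merged into stockpiles: each
prescription is its own episode, the 28-day grace being the stockpile
allowance. Trailing months whose grace window extends past the data
extract end are dropped rather than right-censored, to avoid artificial
cessation inflation at the series tail.

**Initiation.** Indication months are indexed by the qualifying event:
the first risk score at or above the 20% threshold (primary, 28-day
grace) or an incident first cardiovascular event dated at least a year
into follow-up (secondary, 60-day grace, accommodating hospital stays).
Denominators require treatment-naivety at the indication and survival,
registration (at least a year) and — for primary prevention —
event-freedom through the whole grace window.

**Stratification.** Cessation series can be broken down by age group
(40–49 … 80+), sex, diabetes status at the episode end, and duration of
previous continuous prescription. A continuous prescription is a chain
of episodes with no gap above the 28-day grace between the running
maximum end date and the next issue; its duration is measured from the
chain's first issue to the current episode's end and categorised at
182 / 365 / 730 / 1460 days. Duration stratification is restricted to
chains beginning at least a year after registration, so the chain start
is observed rather than censored; consequently the duration-stratified
series is a strict subset of the total (all other stratifications sum
exactly to the unstratified series, which is asserted in tests).

Risk-score bands are closed on the left: a score of exactly 20 falls in
the 20–30 band.

## The regression model

A binomial GLM with logit link on monthly (numerator, denominator)
pairs; the logit link is the only choice under which the reported
quantities are odds ratios. The linear predictor carries an intercept,
a linear month-on-month trend, eleven calendar-month indicators
(January reference — arbitrary but fixed for reproducibility), a level
indicator for the exposure months, and post-exposure terms according to
the model form. Exposure months are retained in the likelihood with
their own level indicator rather than deleted: this keeps the seasonal
terms efficiently estimated while isolating the during-exposure level
from both segments, whose coefficient is reported but not interpreted.
Deletion is available via `drop_during=True`. Months with zero
denominators (possible in sparse secondary-initiation series) carry no
information and are excluded from the likelihood while remaining valid
series rows.

**Autocorrelation.** A single Cochrane–Orcutt-style correction: the
model is fitted once by IRLS, the lag-1 Pearson residuals (first month
set to 0) are appended as a covariate, and the model is refitted. One
refit, not iterated to convergence, keeps the procedure deterministic;
Pearson rather than deviance residuals is a convention choice, logged
here rather than inferred from any source.

**Overdispersion.** The Pearson dispersion `phi = X²/df` of the final
fit scales the covariance; point estimates are untouched (asserted
exactly in tests). Confidence intervals and Wald tests use normal
quantiles on the scaled-SE log-odds scale, the quasi-likelihood
convention of Stata's `glm, scale(x2)`; whether t quantiles would be
preferable on 35 residual degrees of freedom is a genuinely open
choice — the calibration study below shows the normal-quantile test is
adequately calibrated at this series length.

**Convergence.** IRLS with relative tolerance 1e-8 and at most 100
iterations; non-convergence raises. Complete separation (a segment with
all-zero or all-saturated outcomes) is detected before fitting and
raises an error naming the segment, as does a rank-deficient design.

**Curves.** Fitted probabilities and pointwise 95% bands are the
inverse-logit of `eta ± 1.96 se(eta)` with the lagged-residual covariate
set to zero; the counterfactual projection zeroes the during, step and
post-slope coefficients, so it coincides exactly with the fitted curve
on pre-exposure months.

## Effect modification

One joint binomial model per modifier: seasonal and trend terms shared
across strata, stratum main effects, and stratum-specific step terms
via step × stratum interactions — only the step is interacted, since
that is the parameter whose modification is of interest; a fully
interacted variant exists to verify (to 1e-6) that it reproduces
stratum-by-stratum separate fits. The likelihood-ratio test against the
common-step model is computed on fits *without* the lagged-residual
covariate, so both likelihoods are defined on identical covariate sets;
per-stratum odds ratios and intervals come from the lag-corrected,
dispersion-scaled interaction fit. Because the ordinary LRT is
anti-conservative under overdispersion, a dispersion-adjusted statistic
`LRT/(df · phi)` is reported alongside and the p-value is flagged when
`phi > 1.5`. Ordinal modifiers additionally get a scored linear-trend
contrast (equally spaced integer scores by default) replacing the free
interactions, tested by Wald. The binary duration contrast re-aggregates
the five duration bands into under/over one year (the six-months-to-one-
year band on the short side) with exact count conservation.

## Impact calculation

Excess stoppers = Σ over the first six post-exposure months of
(fitted − counterfactual) × monthly denominator, summed over the
primary- and secondary-prevention cessation fits; negative monthly gaps
are retained so the sum is unbiased. National scaling divides by the
database coverage fraction (default 0.069). Excess events over a
10-year horizon:

```
central     = stoppers × (1 − restart) × attrition × risk × rrr
pessimistic = stoppers × attrition × risk × rrr
```

with defaults restart = 0.66 (all-or-nothing protection on restart),
risk = 0.20, rrr = 0.19, and a background-attrition factor of 0.766 —
the share of stopper person-time still at risk of benefit after
accounting for patients who would have stopped or died over the horizon
regardless. The attrition factor is a configurable assumption, not an
estimate the package produces; rounding to whole events is half-up and
applied only at the final step, so the pessimistic/central ratio is
exactly `1/(1 − restart)` under flat attrition.

## Synthetic data

**Series level** (`generate_series`): monthly numerators are binomial
(or beta-binomial) draws around a segmented logit with exactly the
model's structure — baseline, trend, sum-to-zero calendar-month offsets
(a sine harmonic by default, identifiable and easy to zero out), a
during-exposure level, a post-exposure step and slope change — plus
stationary AR(1) noise on the latent logit (matching the lag-1
correction being tested) and beta-binomial inflation with a single
dispersion factor `phi` (the simplest mechanism giving Pearson
dispersion > 1; requires `phi` below the smallest denominator).
Default denominators are 180 000/month, the scale of a national
database's cessation series; initiation-scale runs use ~1 400/month.

**Patient level** (`generate_population`): ~2 000–6 000 patients by
default with uniform ages 45–85, registration 1–10 years before the
study, exponential death/transfer/event/risk-score hazards, and
prescribing as discrete renewal chains (28/56/84-day supplies at
weights 0.7/0.2/0.1, renewal gaps uniform on 0–21 days so renewals stay
inside the grace window). Cessation is a per-renewal Bernoulli whose
log odds carry the same baseline/trend/seasonal/step structure as the
series generator, so the cohort engine's output has a known segmented
truth; tests confirm the configured step and trend survive the full
record-stream → episode → series reconstruction. The simulator does
*not* emulate realistic demography, code vocabularies, comorbidity
correlation, dose titration or informative drop-out — passing tests
show the pipeline's logic and the estimator's calibration, not fidelity
to any real population.

## Validation and problem sizes

The tests and `scripts/acceptance.py` use: 200 replicates per
parameter-recovery condition (Monte-Carlo SE of the mean step OR
≈ 0.0004 at the cessation scale, so 3-SE recovery checks are sharp);
1 000 null replicates for the type-I error of the step Wald test
(measured 5.8% at nominal 5%, within the 3.5–6.5% acceptance band —
slight inflation is expected since the dispersion is estimated on ~35
degrees of freedom and normal quantiles are used); 200 replicates for
interval coverage (measured 93.5%); and populations of 300–6 000
patients for the cohort engine. Larger runs change none of the logic;
these sizes keep the full suite under a minute of simulation time.

## Known limitations

- The lagged-residual correction is a single refit; strong
  autocorrelation (rho well above ~0.7) would be only partially
  absorbed.
- Dispersion scaling uses one scalar; no HAC/robust alternatives.
- The LRT under heavy overdispersion is flagged, not corrected; treat
  flagged interaction p-values with caution.
- The impact calculation assumes causality and all-or-nothing
  protection; it propagates no statistical uncertainty from the fit.
- Patients contributing multiple episodes per month are treated as
  independent binomial trials, as the cohort definition intends; any
  within-patient correlation surfaces as overdispersion.
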