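# Methods

## Estimands and design

The package emulates a target trial of statin initiation within 90 days of an
incident stroke versus non-initiation. Day 0 is the index stroke; the
initiation window is the closed interval [0, 90]; time at risk starts on day
91 and is split into 30-day intervals, interval *t* covering days
[91 + 30(t−1), 90 + 30t]. Two observational contrasts are estimated:

* **ITT analogue** — initiation versus no initiation, ignoring later changes;
  exposure enters the outcome model as the baseline group indicator A0.
* **PP analogue** — sustained use versus no use; follow-up is artificially
  censored at the day a patient deviates from the initial strategy
  (for initiators, the expected end of the last prescription's days-supply
  plus a 90-day grace period; for non-initiators, the first statin
  prescription after the window), and persistence weights correct the
  selection this censoring induces.

Identification rests on the usual sequential-ignorability assumptions: no
unmeasured baseline confounding given L0, selection into the 90-day-survivor
population ignorable given (L0, A0), and censoring/deviation ignorable given
(L0, A0, L_t). The control-outcome and indirect-adjustment machinery exists
precisely because the first assumption is untestable in real data.

## Weight estimation

All four weight components are main-effects logistic regressions on named
covariate roles (demographics, comorbidities, lifestyle, deprivation, stroke
subtype, utilisation, plus the time-varying deterioration state at interval
level). Fitted probabilities are clipped to [1e−6, 1−1e−6] before ratio
formation. Interval-level models include follow-up time as a restricted cubic
spline with 4 knots at the 5/35/65/95 percentiles of the observed interval
index (options: linear, 6-month bins, per-interval dummies, none). Censoring
weights model death/transfer only; administrative censoring (data end, 10-year
cap) is treated as non-informative. Persistence models are fitted separately
per exposure group because deviation means opposite actions in the two groups.
Numerators condition on (A0, time) by default; an option adds L0 to the
censoring numerator. Degenerate situations (no losses, no censoring events, a
group without deviations) yield unit weights with a warning rather than an
error, so nested models collapse exactly in the corresponding limits.

**Interval alignment of cumulative weights.** Within an interval the outcome
takes precedence over censoring (an event is never discarded because death or
deviation fell in the same 30 days). Consistent with that convention, every
person-interval is an at-risk row of the outcome model — including terminal
censored intervals, recorded event-free — and the cumulative weight attached
to a row at interval *t* is the product of the stabilised factors for
intervals 1..t−1, i.e. the inverse probability of remaining uncensored through
the *start* of *t*. Attaching the factor for interval *t* itself (the
convention appropriate when censoring is resolved before the outcome within an
interval) would differentially over-weight event rows in strata with a high
censoring hazard and bias the hazard ratio away from the null; this was
verified numerically against an exact-recursion oracle during development.

**Truncation.** The final combined weight per adjustment level is truncated at
the 1st/99th percentiles computed over all person-intervals entering that
outcome model (options: 0.5/99.5 percentiles, fixed [0.1, 10], none).
Percentile bounds are computed on the combined product, not per component.

## Outcome models

The weighted pooled logistic model regresses the interval event indicator on
A0 and the time spline. Parameters are obtained by a Newton solver with
step-halving written for this package: person-interval tables run to millions
of rows and the general GLM machinery allocates several design copies per
iteration, which matters under modest memory; the solver is verified against
statsmodels' GLM to 1e−8 in the test suite, and statsmodels remains in use for
patient-level models elsewhere. Convergence tolerance is 1e−8 on the maximum
coefficient change with at most 100 iterations; a diverging likelihood is
reported as non-convergence and, when a coefficient passes |β| > 15, as
suspected separation with the offending covariate named. Variances are
cluster-robust sandwiches with scores summed within patients and the
G/(G−1)·(N−1)/(N−k) small-sample factor, matching the standard
cluster-covariance convention (verified against statsmodels).

Person-years accumulate in exact days/365.25 from day 91 to the event or
censoring day.

## Synthetic cohort generator

The generator emulates the statistical structure of a UK primary-care
new-user stroke cohort:

* **Baseline covariates**: age N(71.9, 12.5²), sex, six comorbidity flags,
  three-category smoking, BMI, IMD quintile, consultation count, stroke
  subtype (ischaemic/unspecified/haemorrhagic ≈ 0.475/0.432/0.093; unspecified
  is pooled with ischaemic in analysis unless separated).
* **Treatment assignment**: logistic in baseline covariates with the intercept
  calibrated by root-finding to a 56% marginal initiation proportion. High-risk
  covariates (age, heart failure, CHD, AF, haemorrhagic subtype, consultation
  count) carry negative coefficients, so the crude hazard ratio is biased in
  the protective direction — the direction implied by the published crude
  versus adjusted estimates.
* **90-day selection**: a single "gone by day 91" logistic draw in (L0, A0)
  with a constant death/transfer cause split (0.81 deaths), so the
  selection-weight model is exactly well specified. For initiators who die
  inside the window the initiation day is drawn uniformly before death, so the
  observed group label equals the latent assignment.
* **Follow-up**: monthly draws for an absorbing binary deterioration state
  (onset 0.01/month at reference), the outcome processes (dementia baseline
  hazard 0.0025/month with true treatment log-HR ln 0.70; CHD with ln 0.80;
  fracture and peptic ulcer with zero effect), leaving follow-up
  (death/transfer, 0.0055/month at reference, cause split 0.75), and strategy
  deviation (discontinuation 0.02/month, doubled odds under deterioration;
  crossover 0.004/month). Deterioration raises both the outcome hazard and
  the deviation hazards, making the follow-up and persistence weights
  non-trivially informative. Exit-hazard covariate effects are kept moderate
  (log-odds 0.3–0.5) so that cumulative stabilised weights remain well
  distributed — mean ≈ 1, no extreme values — the regime the published weight
  diagnostics describe; under much stronger informative censoring the
  inverse-probability estimator becomes tail-unstable at late follow-up, which
  is a property of the method, not of its implementation.
* **Eligibility violations** are injected at configurable rates (pre-index
  statins 15%, prior dementia 3%, short history 5%, missing BMI 12%, missing
  smoking 1%, prior fracture/ulcer events) so exclusion logic is exercised on
  every cohort.

Every patient draws from a dedicated substream keyed by (seed, stream,
patient id): cohorts are byte-identical across runs and a patient's record is
invariant to cohort size. What the generator does **not** emulate: coded
vocabularies, dose/potency, multi-drug dynamics, recovery from the
deterioration state, treatment effects on deterioration, calendar-time trends,
and measurement error in covariates or outcomes. Passing tests therefore
certify the estimation machinery under a correctly specified, moderately
confounded world — not robustness to the misspecification real data would add.

## Counterfactual oracle

`counterfactual_truth` simulates each oracle patient under both static
strategies (treated from day 0 / never treated) with selection, censoring and
non-persistence switched off, sharing the per-month outcome uniforms between
arms so the two event processes are maximally coupled and the Monte-Carlo
error of the contrast is far below that of independent arms. The marginal
hazard ratio is the exponentiated arm coefficient of a pooled logistic model
with the same restricted-cubic-spline time terms as the factual outcome model
and no covariate adjustment, fitted on the aggregated (arm × month) binomial
cells (the identical MLE at a fraction of the memory). Including the time
terms matches the oracle to the estimand of the time-adjusted factual models;
the within-window initiation-time variation is treated as ignorable because
time at risk starts after the window closes.

## Validation problem sizes

The test suite validates the pipeline at the sizes a desk-scale re-analysis
supports: pooled-logistic/Cox equivalence on 10,000 patients with a rare
(≤0.002/month) homogeneous outcome; recovery of the true marginal hazard ratio
on confounded 20,000-patient cohorts with full persistence, averaging the
Model-3 estimate over three independent cohorts so the check reflects the
estimator rather than single-draw Monte-Carlo chance; negative-control CI
calibration over 50 replicates of 5,000 patients; and weight diagnostics on a
20,000-patient cohort. Structural identities (PP = ITT under perfect
persistence, Models 1–3 coinciding when selection, censoring and
non-persistence are absent, truncation idempotence, indirect-adjustment
self-calibration) are checked exactly.

## Known limitations

* The hazard ratio is non-collapsible; with the rare outcomes simulated here
  the marginal/conditional gap is small, but the oracle and estimator agree on
  the marginal estimand by construction, not by collapsibility.
* The indirect-adjustment CI assumes independent errors between the primary
  and control outcome models although they share patients; a parametric
  bootstrap option carries the same assumption and is provided for width
  checks only.
* Death and transfer are handled as censoring (with weights), not as
  competing events; cumulative-incidence estimands are out of scope.
* Weight-estimation uncertainty is not propagated into the sandwich variance;
  with stabilised, truncated weights the resulting CIs are approximately
  calibrated (verified by simulation) but not exact.
* A single overall weight set is used for subgroup models, so subgroup
  estimates can retain residual confounding within strata.
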