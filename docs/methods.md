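# Methods

## Model and assumptions

The projection rests on a single idea: a future survey wave is a survey
that was scheduled but never fielded, so its values are missing data.
Three assumptions carry the method:

1. **Missing at random.** Non-response in the observed waves and the
   entirety of the future waves are imputable from the observed
   covariates. For future waves this means secular trends continue as
   modelled — imputation cannot anticipate policy shocks.
2. **Smooth secular trends.** The survey year enters every conditional
   model as a continuous term, linear on the logit scale or a restricted
   cubic spline. Projection is extrapolation of that term; the natural
   spline's linearity beyond its boundary knots keeps extrapolated tails
   linear rather than cubic.
3. **Known future demographics.** The age/sex structure of each
   projection year is taken from a population-projection table and
   treated as fixed; its own uncertainty is not propagated.

The imputation engine is fully conditional specification: each
incomplete variable gets a conditional model given all others, and the
chain cycles through them. Within one stream, missing cells are
initialised by resampling observed values of the same variable within
sex stratum; each sweep refits the conditional model on the
originally-observed rows (given the current values of the predictors),
draws parameters to propagate estimation uncertainty, and redraws the
missing cells. Observed cells are never modified.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `MiceConfig.m` | 100 | completed datasets; between-imputation variability needs m ≥ 2 |
| `MiceConfig.iterations` | 10 | sweeps per stream; chain means stabilise well before 10 in the scenarios tested |
| `binary_draw` | posterior | parameter draw for logistic models: N(MLE, inverse observed information) |
| `polytomous_draw` | bootstrap | multinomial draws refit on a resample; avoids the large joint covariance |
| `FutureSampleSpec.n_per_year` | 10,000 | pseudo-sample size per projection year; also the n in the Wilson interval |
| `FutureSampleSpec.mode` | allocate | demographics by largest-remainder allocation (exact match to the projection); `sample` adds multinomial noise |
| Wilson `level` | 0.95 | prediction-interval level |
| spline knots | 3, at the 10th/50th/90th percentile of observed years | with five equally spaced waves: first, middle, last wave |

Indicator cut-offs (all inclusive): SBP ≥ 140 mmHg, DBP ≥ 90 mmHg,
total cholesterol ≥ 5 mmol/l, HbA1c ≥ 48 mmol/mol, BMI 25 and
30 kg/m². The smoking recency window defaults to 30 days ("smoked
within the last month counts as current"); the source questionnaires do
not pin the cut, so it is configurable.

## Model selection

Candidate predictor sets combine the mandatory core (age, sex, year)
with optional covariates and the other risk factors, searched
exhaustively (≤ 2⁸ subsets; a forward-stepwise flag exists for larger
spaces) on complete cases of the observed waves, scored by
BIC = k ln(n) − 2 ln(L). The year form (linear vs spline) is compared by
BIC within the winning set. Selection precedes imputation and uses
complete cases only — an approximation, since selection on imputed data
would be circular. The non-linearity decision could equally be a
likelihood-ratio test; BIC is used throughout for internal consistency.

## What the synthetic generator emulates — and what it does not

Emulated: five waves (1997–2017), published invited sizes and
questionnaire response rates per sex; uniform ages 25–64 in five areas;
logit-linear indicator trends calibrated so the age-and-obesity-mixed
population prevalence hits the published 1997 and 2017 values per sex
(endpoint logits solved by `brentq`, linear in between); a 3-category
multinomial-logit BMI trend; obesity raising diabetes (log-OR 1.0,
consistent with the reported ~3× risk in the overweight/obese) and
hypertension (log-OR 0.5); diabetes emitted as medication flag + HbA1c
value (80% of diabetics medicated, matching "every fifth case found
only by HbA1c"), so the structural absence of HbA1c in 1997/2007
propagates into mostly-missing derived diabetes there; unit non-response
on a logit model calibrated to the published response rates; item
non-response MCAR at a flat 2% by default (per-variable rates were not
published), with an optional age/sex-dependent (MAR) mechanism, since
MAR is what imputation actually assumes.

Not emulated: real Finnish geography or sampling design, laboratory
measurement error, within-person correlation of measurements, the true
per-variable item-response patterns, and any non-logit-linear trend
shape. Passing tests therefore show the pipeline recovers the truth of
a correctly specified generating model; they cannot show robustness to
misspecification on real data.

Determinism: one master seed; per-wave and per-mechanism substreams are
derived through `SeedSequence(seed, spawn_key=(year, stage))`, so adding
a wave or toggling non-response never perturbs the other draws.
Imputation streams are spawned per imputation index, so results are
invariant to execution order.

## Numerical choices

* **Separation / rank deficiency.** If the Newton MLE fails to converge,
  any coefficient exceeds 50, or the design is rank-deficient, the fit
  falls back to an L2-penalised logit (λ = 10⁻⁴ n, intercept
  unpenalised), flagged on the fit object and logged. Sparse cells are
  expected once future pseudo-samples enter the frame.
* **Posterior draws.** Non-positive-definite covariances are repaired by
  eigenvalue clipping before the Cholesky factorisation (logged).
* **Multinomial fallback.** A degenerate multinomial fit degrades to
  one-vs-reference ridge logits.
* **Wilson interval.** Computed from the closed form and clamped to
  [0, 1] against floating-point spill at p near 0 or 1.
* **Bootstrap category coverage.** Bootstrap resamples for the
  polytomous draw are redrawn (up to 100 times) until every category
  appears.
* **Ties in BIC** (within 10⁻⁹): smaller model wins, then lexicographic
  predictor order.
* **Change tables** compute relative changes from unrounded prevalences
  and round only on output; a zero base yields a missing relative change
  with a warning.
* **Largest-remainder allocation** turns projection weights into integer
  pseudo-sample counts that match the target total exactly.

## Design choices where the design was open

* Derived indicators (binary/3-category), not raw measurements, are the
  imputation targets; the samplers are exactly the binary/categorical
  families the method calls for.
* Area, marital status and education on future rows are imputable
  targets like any other variable (a fixed-marginal alternative exists
  for area-free analyses).
* Visit order defaults to ascending missingness fraction (stabilises
  early sweeps) and can be pinned per variable.
* The Wilson n is the per-stratum pseudo-sample size (5,000 per sex at
  the default 10,000 per year). Whether prediction intervals should also
  absorb between-imputation variance is genuinely open; both quantities
  are emitted, neither is merged.
* Diabetes with no medication in an HbA1c-free wave is *missing*, not 0:
  coding 0 would drag the early-wave prevalence down and bias the trend.

## Problem sizes used in tests and the acceptance script

The package defaults are the full study conditions (m = 100, 10
iterations, 10,000 persons per projection year, annual 2020–2040 grid).
The test suite and `scripts/acceptance.py` run the same code at reduced
sizes chosen as the package's own test scale: m = 10–20, waves of
2,000–3,000 invited (the polarisation scenario keeps the study's
10,000-per-wave scale because extrapolation to 2040 doubles any sampling
noise in the fitted year slope), future pseudo-samples of 2,000 on a
5-year grid. All statistical assertions use 3-standard-error or
stated-percentage-point tolerances against closed-form ground truth of
the generating model.

## Known limitations

* Prevalence pooling averages proportions; full Rubin rules (within +
  between variance) are not applied to the interval itself — the Wilson
  band is a sample-size statement, not a posterior.
* Model selection on complete cases ignores the information in
  incomplete rows.
* The engine imputes binary/categorical variables only; continuous
  samplers (e.g. predictive-mean matching) are out of scope.
* No survey weights: the generator's invited samples are treated as
  simple random samples of the target population.
* Extrapolation is only as good as the logit-linear (or spline-linear)
  trend assumption; the spline's boundary-linear tails limit, but do not
  remove, extrapolation risk.
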