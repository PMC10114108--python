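# Methods

`povmsm` estimates the short-term causal effect of household poverty on
common mental disorder (CMD) from annual household panel data, using
double-robust marginal structural modelling. This note documents the model,
the synthetic data-generating process used to validate it, the numerical
choices, and the known limitations.

## Estimand and identification

The exposure A_t is relative after-housing-costs (AHC) poverty: equivalized
household income below 60% of the contemporaneous median. The outcome Y_t is
CMD caseness, a GHQ-12-style screening score of 4 or more. The target is the
causal risk difference at each wave,

    RD = E{ P(Y_t=1 | A_t=1, W_t) − P(Y_t=1 | A_t=0, W_t) },

the contrast in CMD probability if the current wave's poverty status were
set to 1 versus 0, averaged over the population distribution of the
confounders W_t. This is a *short-term* estimand, conditional on the
previous year's exposure: it is not the effect of persistent poverty.

The adjustment set W_t contains: time-invariant confounders (gender,
ethnicity, education); the time-varying confounders measured at t−1
(welfare benefits, housing tenure, marital status, number of children,
region, SF-12 physical and mental component scores); employment at both t
and t−1 (income consequences of job change are immediate, so current
employment is a confounder rather than a mediator); prior exposure A_{t−1}
and prior outcome Y_{t−1} (health selection); age and age²; and the survey
wave as a categorical period marker.

## Estimation

1. **Stabilized IPT weights.** A pooled logistic exposure model
   P(A_t=1 | W_t) is fitted on all usable person-waves (the weight
   denominator); the numerator is P(A_t=1 | wave). The stabilized weight is
   the ratio evaluated at the observed exposure. The wave-only numerator
   keeps the exposure's time trend in the numerator while letting the
   weights balance *all* adjusted covariates marginally, including prior
   poverty and prior caseness — which is what the balance diagnostics
   check. A P(A_t | A_{t−1}, wave) numerator is also supported
   (`ExposureModelSpec.numerator`), but it deliberately retains the
   lagged-exposure dependence in the pseudo-population and therefore leaves
   lagged covariates marginally imbalanced by construction; it is not the
   default. Weights are per-observation, not cumulative products: the
   estimand is a single-wave contrast and past exposure is
   regression-adjusted.

2. **Balance diagnostics.** Standardized mean differences (weighted
   means/variances, population ddof so integer weights replicate rows
   exactly) before and after weighting, flagged at |SMD| ≥ 0.1 and ≥ 0.2,
   with a love plot. Categorical covariates are expanded level by level.

3. **Double-robust outcome model and g-computation.** The outcome model is
   a pooled logistic regression of Y_t on A_t and the full W_t, fitted with
   the stabilized weights. Each row's outcome probability is predicted with
   A_t forced to 1 and to 0, and the weighted averages are differenced
   (×100 → percentage points). The estimate is consistent if *either* model
   is correct: with correct weights, exposure is independent of W in the
   pseudo-population and the weighted-score equations make the
   standardized contrast consistent even under an outcome-model
   misspecification; with a correct outcome model, weighted maximum
   likelihood remains consistent under arbitrary (positive) weights.

4. **Reported measures.** Risk difference (percentage points); odds ratio
   (the exposure coefficient — a conditional OR; the marginal OR implied by
   the standardized prevalences is stored in metadata because the two
   differ under non-collapsibility); prevalence in the unexposed (the
   forced-to-0 standardized prevalence); and the population attributable
   fraction PAF = 100·(prev_total − prev_unexposed)/prev_total, with
   prev_total the weighted model-predicted prevalence at observed
   exposures. This makes the PAF internally consistent with the risk
   difference and the exposure prevalence by construction; it can be
   negative for a protective exposure.

5. **Uncertainty.** A person-level (cluster) bootstrap: individuals are
   resampled with replacement with all their waves, and the *entire*
   weighting + estimation pipeline is re-run per replicate. SEs are
   replicate standard deviations; CIs are normal (point ± 1.96·se) by
   default, percentile optionally. Default 500 replicates; at least 100
   are required for a reported CI.

6. **Transitions and strata.** Transitions into poverty are estimated on
   the subpopulation with A_{t−1}=0 (exposure = entering), transitions out
   on A_{t−1}=1 (exposure = leaving), with weights refit on the restricted
   sample. Stratified analyses (gender; education; age dichotomized at
   25–40 vs 41–64, assigned per row at time t) refit weights within
   stratum and drop the stratifier from the covariate sets.

7. **Multiple imputation.** Chained equations with plain regression draws:
   continuous variables by Bayesian linear regression (posterior σ², β
   draws plus residual noise), binary by logistic regression with an
   approximate posterior β draw and a Bernoulli draw, ordinal by
   sequential threshold logits. No predictive-mean matching (adequate for
   the synthetic validation data; PMM is a possible extension). Variables
   cycle in fixed order of ascending missingness for a fixed 10 iterations
   with a per-variable mean-of-imputed trace rather than a formal stopping
   rule. Income is log-transformed before imputation; poverty and caseness
   are re-derived (dichotomized) from imputed income/score afterwards.
   Rows missing more than 9 of the 22 analysis variables (16 raw columns
   plus 6 previous-wave values) are excluded before imputation, with a
   log. Estimates are bootstrapped within each imputed dataset and
   combined by Rubin's rules (point = mean; total variance = within +
   (1+1/m)·between).

8. **Fixed-effects comparator.** A conditional (Chamberlain) fixed-effects
   logit, with and without the lagged time-varying confounders. The
   conditional likelihood denominator — a sum over all outcome sequences
   with the observed per-person total — is computed by dynamic programming
   over (wave, running total) in log space, never by enumeration.
   Time-invariant covariates cancel and are dropped. Only
   outcome-discordant individuals contribute. The exposure OR is the
   primary output; an absolute-probability contrast is only available
   under an arbitrary fixed-effect-at-zero convention and is labelled as
   such, because predicted probabilities are not identified from the
   conditional likelihood alone.

## Synthetic data generator

The generator emulates a UK-style annual household panel so every stage is
testable without restricted-access survey data. Design principles:

* **DAG-faithful.** The income and CMD equations use *only* variables in
  the adjustment set (invariants; lagged time-varying confounders;
  employment at t and t−1; A_{t−1}, Y_{t−1}; age terms), so the adjustment
  set is sufficient by construction. Confounder *dynamics* (employment
  persistence, benefit dependence on employment, etc.) may use anything at
  t−1.
* **Exactly-logistic propensity available.** Log equivalized AHC income is
  linear in the adjustment set plus additive logistic noise; since the
  poverty line is 60% of the within-wave median (a constant per wave,
  absorbed by the wave dummies), P(A_t=1 | W_t) is *exactly* a logistic
  model in the default design matrix when the latent AR(1) income
  deviation is switched off (`IncomeParams.ar1 = 0`). This is what makes
  "correct weight model" a well-defined arm in the double-robustness
  experiments. The default keeps a modest ar1 = 0.25 for realism (income
  shocks persist); the outcome model remains exactly correct either way.
* **Health selection.** Prior caseness lowers income
  (`selection_effect`, default 0.20 on log income; the strong_selection
  scenario uses 0.80) and lowers re-employment probability, generating the
  reverse-causation structure that biases crude associations.
* **Calibration.** The income noise scale (0.27) and baseline CMD logit
  (−1.62) were calibrated once so the default scenario reproduces the
  population margins of a UK working-age panel after imputation: ~22%
  poverty and ~20% CMD prevalence; they are fixed thereafter and guarded
  by a regression test. Coefficient magnitudes were chosen so that
  (a) confounding is strong (crude risk difference ~13pp against a true
  ~2.2pp) and (b) exposure overlap remains healthy (stabilized weights
  with mean ≈ 1 and single-dataset maxima in the tens, not thousands).
* **Default effect size.** `exposure_effect = 0.16` on the latent logit,
  i.e. a conditional OR ≈ 1.17 and a marginal risk difference ≈ 2.2
  percentage points at 20% baseline prevalence — the scale of effect this
  class of study reports. An onset-only variant
  (`exposure_effect_persist = 0`) lets transition experiments separate
  entering poverty from remaining in it.
* **Household structure** is minimal: one respondent per household, a
  partner entering only through the modified-OECD equivalence scale
  (1.0 + 0.5·partner + 0.3·child) and a coupled-income premium; housing
  costs are a person-specific fraction (mean 25%) of gross income. Region
  is a 4-level categorical with no causal role (a pure noise covariate).
* **GHQ-12** is generated as latent-logit caseness directly; a score 0–12
  consistent with caseness is emitted for the derivation code path, not as
  an item-level instrument simulation.
* **Missingness**: cell-level MAR with probabilities depending only on
  *other, observed* covariates of the row (never the cell's own value),
  intercept-calibrated to the target marginal rate; attrition is monotone
  (once gone, gone).
* **Oracle truth** is Rao-Blackwellized: at every eligible person-wave the
  exposure is forced to 1 and 0 with history at natural values and the
  outcome-*probability* contrast is averaged, giving Monte-Carlo SEs far
  smaller than simulating outcomes. Transition truths are computed on the
  same restricted reference populations the estimators use. The reported
  `mc_se` is person-clustered.

What the generator does **not** emulate: survey design (clustering,
stratification, longitudinal weights), item-level instruments, multi-person
households, national (as opposed to within-sample) poverty lines, and real
geography. Passing tests therefore demonstrate the statistical machinery
under the assumed causal structure, not robustness to survey artefacts.

## Numerical choices

* Logistic fits use Newton/IRLS with step-halving on the log-likelihood, a
  1e-8 L2 stabilizer (keeps quasi-separated fits — rare indicator levels
  with no events — finite and convergent; shifts identified coefficients
  by O(1e-6) at most, verified against statsmodels), collinear-column
  dropping via a pivoted Gram-Schmidt rank check, and an explicit
  complete-separation error (raised when the linear predictor perfectly
  classifies the outcome) naming the offending covariate.
* Cluster-robust covariances are person-level sandwich estimators with a
  G/(G−1) correction.
* Positivity: fitted denominator probabilities of the observed exposure
  below 1e-6 raise an error listing the rows, rather than silently
  producing enormous weights. Weight truncation is off by default; an
  optional percentile pair clamps the tails.
* Poverty line: even-count median is the mean of the central pair; the
  median is person-weighted (over person-wave rows); ties at the line are
  unexposed (strict `<`). Lags require consecutive observed waves — a
  skipped wave breaks the lag chain. The working-age filter (25–64) is
  applied per row.
* The conditional-logit optimizer is L-BFGS-B on the DP log-likelihood
  with numerical gradients and an explicit numerical Hessian at the
  optimum; per-person scores (central differences) feed the sandwich.
* Pipeline stage seeds are derived from the global seed by CRC-32 hashing
  of the stage name, so adding a stage never perturbs earlier stages.

## Validation problem sizes

The test-suite experiments run at deliberately modest, fixed sizes chosen
as the package's own validation conditions: oracle-recovery and
crude-bias checks at n = 5000 persons × 6 waves over 50 replicates
(oracle at 100 000 Monte-Carlo individuals); null-coverage at n = 1000 × 4
waves over 200 replicates with 150 bootstrap replicates; double-robustness
at n = 4000 × 5 waves over 40 replicates per arm; the missing-data repair
experiment at n = 1500 × 4 waves over 20 replicates with m = 5. The
acceptance script reproduces the full pipeline at n = 4000 × 6 waves with
m = 5 imputations and 200 bootstrap replicates.

## Limitations

* The probability contrast after conditional fixed-effects logit is not
  identified; the reported value fixes the person effect at zero and is
  labelled approximate.
* The OR the pipeline reports is conditional on covariates;
  non-collapsibility means it is not the marginal OR (also reported, in
  metadata).
* MI uses single-row predictors (plus declared interactions); it does not
  borrow within-person longitudinal structure beyond the lag columns.
* The bootstrap treats persons as independent; household clustering
  beyond the person is not modelled (households are persons here).
* Regression-draw MI without PMM can generate mild tail artefacts for
  strongly non-normal continuous variables (income is log-transformed to
  mitigate this).
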