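# povmsm

Double-robust marginal structural models for estimating the causal effect
of household poverty on common mental disorder (CMD) in longitudinal
household panels — with a calibrated synthetic panel generator and
counterfactual oracle, so the whole pipeline is testable end to end without
restricted-access survey data.

**Who it is for.** Epidemiologists and social scientists analysing annual
panel surveys (UKHLS-style data) where a time-varying exposure (relative
poverty) and a time-varying outcome (GHQ-12 caseness) confound each other
over time: poor mental health depresses future income (*health selection*),
so naive regression — and even fixed-effects regression — can badly mis-state
the causal effect. Marginal structural models with inverse probability of
treatment weighting handle exactly this feedback structure.

## The model

* **Exposure** A_t = 1 if equivalized after-housing-costs household income
  is below 60% of that wave's median (modified-OECD equivalence scale,
  strict inequality at the line).
* **Outcome** Y_t = 1 if the GHQ-12 screening score is ≥ 4 ("caseness").
* **Estimand** — the causal risk difference at each wave,
  `E{P(Y=1|A=1,W) − P(Y=1|A=0,W)}`, with W the adjustment set: gender,
  ethnicity, education; lagged employment, benefits, tenure, marital
  status, children, region, SF-12 physical/mental scores; employment at t;
  prior poverty and caseness; age, age²; survey wave.
* **Estimator** — stabilized IPT weights from a pooled logistic exposure
  model, applied to a covariate-adjusted pooled logistic outcome model
  (double-robust), with g-computation standardization for the marginal
  risk difference, the prevalence in the unexposed, and the population
  attributable fraction `PAF = 100·(prev_total − prev_unexposed)/prev_total`.
  Uncertainty by person-level bootstrap re-running the whole pipeline;
  missing data by chained-equations multiple imputation with Rubin
  pooling; sensitivity comparison by conditional fixed-effects logit
  (Chamberlain likelihood, dynamic-programming denominator).

See `docs/methods.md` for the full statistical account.

## Worked example

```python
from povmsm import (scenario, generate_panel, derive_poverty,
                    build_analysis_table, compute_stabilized_weights,
                    estimate_effect, estimate_transitions,
                    compute_oracle_truth)

cfg = scenario("default", n_individuals=5000, n_waves=6, seed=7)
panel = generate_panel(cfg)                      # long person-wave panel
table = build_analysis_table(derive_poverty(panel))
weights = compute_stabilized_weights(table)
effect = estimate_effect(table, weights)
truth = compute_oracle_truth(cfg, n_mc=100_000)

print(f"risk difference: {effect.rd:.2f} pp   odds ratio: {effect.or_:.2f}")
print(f"prevalence in unexposed: {effect.prev_unexposed:.2f}%   PAF: {effect.paf:.2f}%")
print(f"oracle truth: {truth.true_rd:.2f} pp")
```

prints

```
risk difference: 2.12 pp   odds ratio: 1.16
prevalence in unexposed: 19.74%   PAF: 2.32%
oracle truth: 2.23 pp
```

The estimated risk difference (2.12 percentage points) recovers the
generator's known counterfactual effect (2.23 pp) to well within sampling
error at this n: being in poverty raises the probability of CMD caseness by
about two percentage points on a baseline of ~20%, an odds ratio of ~1.17.
The PAF says ~2.3% of CMD burden in this synthetic population is
attributable to current poverty. Transition-specific estimands
(`estimate_transitions(table, "into")` / `"outof"`), stratified effects
(`estimate_stratified`), bootstrap CIs (`bootstrap_estimate`), multiple
imputation (`mice_impute`, `pool_rubin`) and the fixed-effects comparator
(`fit_conditional_logit`) follow the same pattern.

The crude (unweighted, unadjusted) association in the same data is ~13 pp —
six times the causal effect — which is the health-selection bias the
weighting removes. Balance diagnostics confirm it: every adjusted
covariate's post-weighting |SMD| is below 0.04
(`balance_table(table, weights)`).

## Command line

```bash
povmsm estimate --n 5000 --waves 6 --seed 7 --out results/
povmsm reproduce --n 4000 --seed 1 --out results/   # full experiment: MI,
                                                    # transitions, strata, FE
povmsm report --out results/
```

Subcommands: `simulate`, `derive`, `impute`, `weight`, `estimate`,
`transitions`, `strata`, `fe-compare`, `reproduce`, `report`; flags include
`--config` (YAML run config), `--m`, `--bootstrap-n`, `--no-impute`
(complete-case mode). Outputs are tidy CSVs (results, balance), a love
plot, a weight summary and a JSON manifest that suffices to re-run the
bundle exactly.

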