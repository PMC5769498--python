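# emtdx

Evaluation toolkit for a continuous primary-tumor marker used as a third
binary diagnostic test of cancer-cell detachment, alongside lymph-node
evaluation and radiologic imaging. Two complementary analyses:

1. **Diagnostic accuracy without a gold standard** — a Bayesian three-test
   latent-class model with a probit link and a shared standard-normal random
   effect inducing conditional dependence between test errors. Marginal
   sensitivity/specificity of test *j* in class *d* is
   `Phi(a_dj / sqrt(1 + c_dj^2))`. Eight dependence structures are fitted,
   from fully independent (all six loadings zero) to fully dependent, with
   six partial structures (one or two tests constrained). The 8-cell pattern
   likelihood is evaluated by Gauss–Hermite quadrature, and the posterior is
   explored by a seeded Metropolis-within-Gibbs sampler parameterized
   directly on (prevalence, Se, Sp, loadings) with uniform priors on the
   accuracy scale (informative Se 60–70% / Sp 95–99% for the established
   tests, flat for the marker).
2. **Prediction increment** — Cox proportional-hazards models (Breslow ties
   and baseline) of 5-year all-cause mortality for a base model (lymph node
   + imaging, imputed from TNM stage) vs the base model plus the marker
   (continuous or dichotomized); compared via the censored-outcome c-index,
   event / non-event NRI, IDI, a Hosmer–Lemeshow-type reclassification
   calibration statistic, risk stratification tables, and percentile
   bootstrap intervals with both models refitted per replicate.

A synthetic-cohort module generates cohorts with known latent truth
(including a 188-subject preset calibrated to published marginal test
counts and death counts), so the entire pipeline is testable without the
original subject-level data, which was never deposited.

## Layout

| module | contents |
| --- | --- |
| `emtdx.cohort` | subject records, CSV I/O, area-weighted core averaging, marker dichotomization, stage→test imputation, pattern counts |
| `emtdx.latent` | dependence specs, priors, quadrature likelihood, MCMC fit, model suite |
| `emtdx.survival` | Breslow Cox fit, absolute 5-year risk, Harrell c-index, risk distribution summaries |
| `emtdx.reclassification` | risk categories, stratification table, NRI/IDI, calibration, bootstrap |
| `emtdx.synthetic` | generative model, theoretical pattern probabilities, calibrated preset |
| `emtdx.pipeline` / `emtdx.cli` | orchestration, reports, command line |

## CLI

```bash
# synthetic cohort CSV + hidden truth
emtdx simulate --preset cancors-like --seed 1 --out results/

# latent-class accuracy across 8 dependence models x 3 cut points
emtdx accuracy --preset cancors-like --seed 1 --out results/

# prediction increment with bootstrap CIs
emtdx predict --preset cancors-like --seed 1 --out results/

# cut-point scan (defaults to every distinct observed marker value)
emtdx scan --preset cancors-like --seed 1 --out results/ --no-accuracy
```

Use `--config config.yaml` to set priors, the MCMC schedule, risk-category
cut points, bootstrap replicates, and input CSV paths (`cohort_path`,
`cores_path`); `--cutpoints 0.52,0.6,0.85` and `--models` override
individual fields. All randomness flows from `--seed`; identical
config + seed gives byte-identical reports. Exit code 2 signals a
configuration/validation error, 3 a numerical failure.

Input CSV columns: `subject_id, stage, n_stage, marker_score,
followup_time_years, death` with optional `ln_test`/`ri_test` (otherwise
imputed from stage: local → both negative; regional → node-positive; distant
→ imaging-positive with node status from N-stage). A companion long-format
cores CSV (`subject_id, core_intensity, core_area`) may replace
`marker_score` via area-weighted averaging. Binary tests are coded
1 = positive (evidence supporting detachment).

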