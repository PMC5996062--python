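# ohga — oral health and general health dynamics in older home-care cohorts

`ohga` implements a two-stage Bayesian analysis of the relationship between
oral-health (OH) and general-health (GH) indicators in longitudinal
home-care assessment data, together with a synthetic cohort generator that
emulates a Belgian home-care registry (~8,400 older adults assessed roughly
every six months), so the whole pipeline runs and is tested without access to
the restricted registry.

**Who it is for.** Biostatisticians and epidemiologists studying
cross-sectional and cross-lagged associations between binary symptom
indicators (here: non-intact teeth NT, chewing difficulty CD, dry mouth DM)
and ordinal health scales (ADL 0–6, CPS 0–6, DRS 0–14, CHESS 0–5; higher =
worse), and anyone needing a reproducible reference implementation of these
two models with MAR masking and chained Bayesian imputation around them.

## The models

**First analysis — random-effects proportional odds.** Each GH scale `Y`
(categories `0..K-1`) is regressed on the three OH indicators and covariates
via a cumulative-logit model with a normal subject intercept:

```
P(Y_ij <= k | x_ij, b_i) = logistic(alpha_k - x_ij' beta - b_i),   b_i ~ N(0, sigma_b^2)
```

so `exp(beta)` is the odds ratio of poorer general health. Model fit is
summarized by the observed-vs-predicted contingency table (posterior-median
predictions) and the percentage of records predicted exactly / within one
category.

**Second analysis — bivariate ordinal autoregression.** For each (GH, OH)
pair, the two responses at a visit are modeled jointly with their values at
the previous visit as regressors:

```
GH:  logit P(GH_j <= k) = alpha_k - (gamma11 GH_{j-1} + gamma12 OH_{j-1} + x'delta1 + u_1)
OH:  logit P(OH_j = 1)  = c2 + gamma21 GH_{j-1} + gamma22 OH_{j-1} + x'delta2 + u_2
```

with `(u_1, u_2)` bivariate normal. `gamma12` is the cross-lagged effect of
current oral health on future general health, `gamma21` the reverse; the 12
pair fits assemble into a directed graph of significant cross-lags.

Both models marginalize their random intercepts by Gauss–Hermite quadrature
and sample the low-dimensional posterior with four independence
Metropolis–Hastings chains (Laplace-based Student-t proposal), checked with
the split-chain Brooks–Gelman–Rubin diagnostic and extended until every
Monte Carlo standard error is below 5% of its posterior SD. Missing data
(~6% GH scales, ~17% OH items, ~23% CHESS, missing at random) are handled by
chained Bayesian imputation into M completed datasets whose posteriors are
pooled. See `docs/methods.md` for the full specification.

## Worked example

```python
import ohga

# a fully observed synthetic cohort of 500 subjects under the scenario whose
# generative model is exactly the proportional-odds analysis
params = ohga.TrueParams.for_proportional_odds()   # CD->ADL odds ratio 3.452
cohort = ohga.simulate_cohort(
    ohga.GeneratorConfig(n_subjects=500, seed=11, true_params=params))

spec = ohga.POModelSpec(response="ADL",
                        mcmc=ohga.MCMCConfig(n_chains=4, n_warmup=150,
                                             n_draws=350, strict=False))
fit = ohga.fit_proportional_odds(cohort, spec, seed=5)
print(ohga.summarize_or(fit, scale="ADL").table)
table, summary = ohga.evaluate_fit(fit, cohort, spec, seed=7)
print(f"exact {summary.pct_exact:.1f}%  within one {summary.pct_within_one:.1f}%")
```

Output (seed 11; 777 assessment records):

```
  scale effect  or_median    ci_low   ci_high
0   ADL     NT   1.369112  0.998458  1.899456
1   ADL     CD   3.515029  2.493290  4.939374
2   ADL     DM   1.397759  0.994997  2.027395
exact 32.0%  within one 74.4%
```

The CD odds ratio of 3.52 (2.49, 4.94) brackets the generator's 3.452: a
subject with chewing difficulty has ~3.5 times the odds of a worse ADL
category. In-sample concordance on this synthetic cohort is far below the
80%+ seen on real registry data, where subject-level persistence is much
stronger; see docs/methods.md on what the generator does and does not
emulate.

The cross-lagged analysis reads analogously:

```python
params = ohga.TrueParams.for_crosslag()            # ADL-CD cross-lags 0.077 / 0.031
cohort = ohga.simulate_cohort(ohga.GeneratorConfig(
    n_subjects=1000, seed=777, true_params=params, fixed_n_visits=4))
pair = ohga.VARPairSpec(gh="ADL", oh="CD", covariates=(), mcmc=spec.mcmc)
fit = ohga.fit_bivariate_var(ohga.build_transition_frame(cohort, pair), pair, seed=5)
est = ohga.summarize_crosslag(fit, "ADL", "CD")
print(est.estimates["gamma12"])
```

prints `(0.088, -0.072, 0.253)` — posterior mean and 95% credible interval
for the CD→future-ADL cross-lag, covering the generator's 0.077.

A full study (simulate → mask → impute → 4 proportional-odds fits →
evaluation → 12 pair fits → association graph) runs from the shell:

```
ohga run --config examples/study.yaml --out results/
```

(`ohga simulate`, `filter`, `mask`, `impute`, `fit-po`, `fit-var`,
`evaluate`, `diagnose` expose the individual stages.)

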