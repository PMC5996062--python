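# Methods

This note documents the statistical models implemented in `ohga`, the
synthetic-cohort generator that stands in for the access-restricted home-care
registry, and the numerical choices behind the fits.

## The data structure

One row per subject-visit ("assessment"), visits roughly six months apart
(1–10 per subject).  Seven indicators are analyzed:

* **Oral health (OH)**, binary, 1 = problem present: non-intact teeth (NT),
  chewing difficulty (CD), dry mouth (DM).
* **General health (GH)**, ordinal interRAI scales, higher = worse/less
  stable: ADL (0–6), CPS (0–6), DRS (0–14), CHESS (0–5).

Baseline covariates: age at baseline, gender, intervention type (case
management / night care / occupational therapy / other).  Time-varying
covariates: living alone, having an informal caregiver.  Inclusion rules:
age at baseline strictly over 65; subjects without a known birth date or with
a missing assessment date are dropped; repeated assessments must fall within
five to seven months (inclusive) of the previous one — a violating visit and
all later visits are dropped by default (a flag keeps later visits instead),
because the autoregressive analysis interprets consecutive visits as one
six-month chain.  Months are `days / 30.4375`, timezone-free.

## First analysis: random-effects proportional odds

For each GH scale `Y` with categories `0..K-1`:

    P(Y_ij <= k | x_ij, b_i) = logistic(alpha_k - x_ij' beta - b_i),
    b_i ~ N(0, sigma_b^2),   alpha_1 < ... < alpha_{K-1}.

Covariates: NT, CD, DM, baseline age (centered at 80, per 10 years), gender,
intervention dummies, time (`visit_index - 1`, half-year units), intervention
x time interactions, living alone, informal caregiver.  The sign convention
puts worse categories at larger linear predictor, so `exp(beta)` is the odds
ratio of poorer general health (OR > 1 = higher risk).  Priors are vague:
`beta ~ N(0, 10^2)`, thresholds as an ordered transform of `N(0, 10^2)`
variables, `sigma_b ~ Half-Normal(5)`.

The subject intercept is integrated out of the sampled posterior with
Gauss–Hermite quadrature (11 nodes by default; adequate for `sigma_b` around
1).  For record-level prediction, `b_i` is re-drawn per posterior draw from
its conditional posterior discretized on the same grid; the predicted
category of a record is the **lower median** of the per-draw sampled
categories.  Model fit is summarized by the observed-vs-predicted
contingency table and the percentage predicted exactly right / within one
category (in-sample, as a goodness-of-fit surface).

## Second analysis: bivariate ordinal autoregression

For one (GH, OH) pair, visits `j >= 2` are modeled jointly given the
previous visit's observed values:

    GH:  P(GH_ij <= k) = logistic(alpha_k - eta1),
         eta1 = gamma11 GH_{i,j-1} + gamma12 OH_{i,j-1} + x' delta1 + u_i1
    OH:  P(OH_ij = 1) = logistic(c2 + gamma21 GH_{i,j-1} + gamma22 OH_{i,j-1}
                                  + x' delta2 + u_i2)
    (u_i1, u_i2) ~ N2(0, [s1^2, r s1 s2; r s1 s2, s2^2])

`gamma12` is the cross-lagged effect of oral health on future general health
and `gamma21` the reverse; `gamma11`, `gamma22` are the autoregressive
effects.  The lagged GH scale enters as its integer score (the model reports
one scalar cross-lag per pair).  The correlated subject intercepts are the
cross-equation coupling; first-visit responses are conditioned on, never
modeled, so no stationarity assumption is imposed at fit time.  Default
adjustment covariates: age, gender, living alone, informal caregiver
(configurable, including none).  A directed graph over the seven indicators
collects the significant cross-lags of all 12 pairs: an edge OH -> GH is
drawn iff that pair's `gamma12` 95% credible interval excludes zero, and
GH -> OH iff `gamma21`'s does.

The bivariate random intercept is marginalized by a tensor Gauss–Hermite
grid (7 x 7 nodes by default), with the correlation absorbed via a Cholesky
transform of the standard grid.  A numba-compiled kernel evaluates this
likelihood; the vectorized numpy implementation is kept as the reference and
the two are asserted equal (to ~1e-11) in the test suite.

## Missingness and imputation

Masking emulates the registry's missingness: about 6% on ADL/CPS/DRS and the
informal-caregiver flag, 17% on the OH items, 23% on CHESS.  The mechanism is
missing at random: the masking probability is `expit(c + 0.5 z)` where `z` is
a standardized score of always-observed predictors (baseline age, gender,
visit index) and `c` is solved so the expected rate equals the target.

Imputation is a fully conditional sequence ordered from least- to
most-missing variable: Bayesian logistic regression for binary variables,
cumulative-logit for ordinal ones, each conditioning on all other analysis
variables plus the baseline covariates and visit index.  Each model is fit by
posterior mode with a normal (Laplace) posterior approximation, and every one
of the M completed datasets (default M = 5) imputes from its own posterior
parameter draw — the standard approximate-Bayesian imputation used by
chained-equation software, chosen here over per-variable MCMC because the
approximation error is negligible next to the sampling noise at these
missingness rates.  Two chained cycles are run per dataset.  Downstream fits
are pooled by concatenating the M posteriors (mixture-of-posteriors pooling
of fully Bayesian fits), so pooled variance = average within-imputation
variance + between-imputation variance of the means.

## Posterior computation

All models marginalize their random effects by quadrature, leaving 14–25
unconstrained parameters (thresholds via log-increments, variance components
via logs, the intercept correlation via atanh).  Sampling is independence
Metropolis–Hastings: a multivariate Student-t proposal (df 7, covariance 1.2x
the inverse negative Hessian at the posterior mode) drives four independent
chains run in lockstep, one batched log-posterior call per iteration.  The
kernel is fixed after warmup (a single moment re-estimation occurs only if
warmup acceptance falls below 15%), so the chains are genuine Markov chains.
Typical acceptance is 40–60%, and because proposals are posterior-wide and
independent, effective sample sizes are a large fraction of the draw count.

Convergence follows the analysis practice being reproduced: four chains,
split-chain Brooks–Gelman–Rubin R-hat (< 1.1; classical, not
rank-normalized, with a flag to enable rank normalization), then sampling is
extended in batches until every parameter's Monte Carlo standard error is
below 5% of its posterior SD (`MCSE = SD / sqrt(ESS)` with autocorrelation-
based ESS).  Draws that are constant across chains define R-hat = 1 and
MCSE = 0.  Failure after the allowed extensions is reported, not raised, so
pipelines can log and halt; model-fit wrappers raise on request (`strict`).

## The synthetic generator

The generator is the generative twin of the two analyses.  Baseline
covariates are drawn from the published registry marginals: age from a
truncated normal on [65, 102] whose location is calibrated so the truncated
mean equals 81.2 (the realized SD is then ~6.8 against the published 7.0 —
the mean is matched exactly, the SD approximately, since both cannot hold
under truncation); 68.3% female; intervention shares 59.43 / 16.43 / 10.95 /
9.29 renormalized to sum to one (the published shares total 96.10%).  The
visit count per subject follows a point mass at one visit mixed with a
truncated geometric on 2–10, calibrated so the mean visits per subject is
13187/8359 ~ 1.578 and the mean among multi-visit subjects is 2.4.  Visit
dates are 153–213 days apart (5–7 months), so generated cohorts pass the
inclusion filters unchanged.  Living alone (55%) and informal caregiver
(78.6%) evolve as two-state Markov chains stationary at those marginals with
a 5% expected per-visit switch probability.

Indicators evolve per visit as: each OH item from a logistic autoregression
(own lag, subject intercept, optionally a cross-lag from its focal GH
partner), then each GH scale from the cumulative-logit model given the
*current* OH values, covariates, its own lag and subject intercept.  Default
effect sizes: the published OH odds ratios per GH scale (e.g. 3.452 for
CD -> ADL) as current-visit effects; age 0.4 per decade, female -0.1, night
care 0.2, occupational therapy 0.1, other 0.15, time 0.1 per half-year,
interactions 0, living alone -0.2, informal caregiver 0.3; own-lags 0.25
(GH, per category) and 0.8 (OH); the ADL–CD pair carries the published
cross-lags (0.077, 0.031) and intercept correlation 0.3.  GH thresholds
derive from plausible marginal category distributions (ADL's from the
published contingency-table margin); OH prevalences are NT 0.45, CD 0.30,
DM 0.25.  Random-intercept SDs default to 1.0 (GH) and 0.8 (OH).  First-visit
states replace the unavailable lags with category midpoints ("uniform
categories" is available as an option).

Three factory scenarios match generator to analysis: `for_proportional_odds`
(no lag dynamics — the first analysis's model exactly), `for_crosslag` (no
covariate effects; one focal pair with configurable gammas), and `null` (all
effects zero).  In `for_crosslag` the first-visit states exclude the subject
intercepts, so that conditioning on visit 1 — which the fitted model does —
is exactly the true conditional law and parameter recovery is free of the
dynamic-panel initial-conditions problem.  The realistic default keeps the
dependence, as in real registries; a cross-lagged model fit to such data
estimates a projection, which is a property of the method, not of this
implementation.

### What passing tests do and do not show

The generator draws from the same parametric families the models assume, so
recovery and calibration tests validate correctness of the implementation —
likelihoods, quadrature, sampler, pooling — under the models' assumptions.
They do not probe misspecification present in real registry data
(non-proportional odds, informative visit schedules, non-normal
heterogeneity, MNAR missingness), which is out of scope.  Absolute
concordance levels are also not comparable to registry analyses: with the
default subject-intercept SD of 1, the synthetic data carry far less
subject-level persistence than real assessment data, where fitted values
track each subject's own history closely, so in-sample exact concordance on
synthetic cohorts sits near 30–40% rather than above 80%.

## Simulation sizes used in the checks

Replicate studies run at sizes chosen to estimate each property with useful
precision: proportional-odds recovery and null calibration at 500 and 400
subjects with the calibrated natural visit mix; cross-lag recovery at 1,000
subjects with four visits and null cross-lag calibration at 400 subjects with
four visits (the cross-lagged model learns only from multi-visit subjects,
and at very short panels the weakly identified variance components alias the
cross-lags — a known small-sample feature of dynamic panel models, visible
here as mild undercoverage at 500 subjects x 3 visits that disappears by
1,000 x 4); imputation checks at 300 subjects with M = 2.  Sampler settings
for replicates: 4 chains x (150 warmup + 350 draws).  Masking-rate fidelity
uses ~10,000 records.

## Numerical details and edge cases

* Ordinal probabilities are computed as `logF(hi) + log1p(-exp(logF(lo) -
  logF(hi)))` with `log_expit`, stable for extreme linear predictors and the
  open-ended categories.
* Thresholds are sampled as (first threshold, log increments); the Jacobian
  is the sum of log increments.  Empirical cumulative logits initialize them.
* The finite-difference Hessian at the mode is symmetrized and its spectrum
  floored to keep the proposal covariance positive definite; evaluations are
  chunked to bound memory.
* Non-finite log posteriors propose rejection rather than raising.
* Lower-median tie-breaking makes predicted categories deterministic given
  the draw sequence.
* Degenerate imputation models (single observed level, separation) fall back
  to marginal posterior-predictive draws.
* An empty transition frame (no subject with two consecutive visits) is a
  model error; an empty cohort filters to an empty cohort without error.

## Known limitations

* The imputation models are Laplace-approximate rather than fully sampled;
  at ~20% missingness and these sample sizes the approximation error is well
  inside Monte Carlo noise (verified by the MCAR-unbiasedness check), but at
  extreme missingness or tiny n full MCMC would be preferable.
* Credible intervals for the cross-lag variance components (`sd_u1`,
  `sd_u2`, `r_u`) are wide on short panels; the cross-lag point estimates
  remain calibrated at the sizes documented above.
* The independence-MH engine relies on unimodal, roughly elliptical
  posteriors — which quadrature-marginalized ordinal mixed models of this
  size have.  It is not a general-purpose sampler.
* Concordance is computed in-sample by design (a goodness-of-fit measure);
  an out-of-sample mode exists but is off by default.
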