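"""Bayesian random-effects proportional-odds regression (first analysis).

Each GH scale Y (ordinal, 0..K-1) is regressed on the three OH indicators and
the covariate set via a cumulative-logit model with a normal subject
intercept:

    P(Y_it <= k | x_it, b_i) = logistic(alpha_k - x_it' beta - b_i),
    b_i ~ N(0, sigma_b^2),  alpha_1 < ... < alpha_{K-1}.

Positive beta shifts mass toward higher (worse) categories, so exp(beta) is
the odds ratio of poorer general health.  Priors are vague: beta ~ N(0, 10^2),
ordered-transformed thresholds ~ N(0, 10^2), sigma_b ~ Half-Normal(5).
The subject intercept is marginalized out of the sampled posterior by
Gauss-Hermite quadrature and re-drawn from its conditional posterior for
record-level prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp

from .cohort import Cohort
from .design import PO_COVARIATES, build_design
from .diagnostics import MCMCConfig
from .sampling import PosteriorDraws, sample_posterior
from .scales import GH_SCALES, OH_INDICATORS, SCALES

__all__ = [
    "POModelSpec",
    "ORTable",
    "cumulative_category_probs",
    "log_likelihood",
    "fit_proportional_odds",
    "summarize_or",
    "posterior_predict_categories",
]


@dataclass
class POModelSpec:
    """Model definition for one GH response."""

    response: str = "ADL"
    covariates: tuple = PO_COVARIATES
    include_random_effects: bool = True
    n_quad: int = 11
    prior_beta_sd: float = 10.0
    prior_alpha_sd: float = 10.0
    prior_sigma_sd: float = 5.0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if self.response not in GH_SCALES:
            raise ValueError(f"response must be a GH scale, got {self.response!r}")
        for ind in OH_INDICATORS:
            if ind not in self.covariates:
                raise ValueError(f"OH indicator {ind} must be among the covariates")

    @property
    def n_categories(self) -> int:
        return SCALES[self.response].n_categories


def cumulative_category_probs(eta: float, alpha) -> np.ndarray:
    """Category probabilities of the cumulative-logit model.

    ``P(Y <= k) = expit(alpha_{k+1} - eta)``; larger ``eta`` moves mass to
    higher (worse) categories.  ``alpha`` must be strictly increasing,
    length K-1.
    """
    alpha = np.asarray(alpha, float)
    if alpha.ndim != 1 or (len(alpha) > 1 and not np.all(np.diff(alpha) > 0)):
        raise ValueError("alpha must be a strictly increasing 1-D threshold vector")
    cum = np.concatenate([expit(alpha - eta), [1.0]])
    probs = np.diff(cum, prepend=0.0)
    return probs


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _ordinal_logprob(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """log(expit(hi) - expit(lo)) computed stably for hi > lo (+-inf allowed)."""
    lhi = log_expit(hi)
    llo = log_expit(lo)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = lhi + np.log1p(-np.exp(llo - lhi))
    return np.where(np.isneginf(llo), lhi, out)


def log_likelihood(spec: POModelSpec, params: dict, cohort: Cohort) -> float:
    """Conditional log-likelihood at one parameter draw.

    ``params`` holds ``beta`` (covariate name -> coefficient), ``alpha``
    (ordered thresholds) and optionally ``b`` (subject_id -> intercept,
    default 0).  The value is the sum over records of the log category
    probability of the observed response given the subject intercept.
    """
    df = cohort.data
    y_col = df[spec.response]
    if y_col.isna().any():
        raise ValueError(f"missing {spec.response} values; impute before evaluating")
    y = y_col.to_numpy(int)
    X = build_design(df, tuple(spec.covariates))
    beta = np.array([params["beta"][c] for c in spec.covariates], float)
    alpha = np.asarray(params["alpha"], float)
    if not np.all(np.diff(alpha) > 0):
        raise ValueError("alpha must be strictly increasing")
    b_map = params.get("b", {})
    b = df["subject_id"].map(lambda s: b_map.get(s, 0.0)).to_numpy(float)
    eta = X @ beta + b
    apad = np.concatenate([[-np.inf], alpha, [np.inf]])
    return float(_ordinal_logprob(apad[y + 1] - eta, apad[y] - eta).sum())


def _gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(Z)], Z ~ N(0,1)."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _po_arrays(cohort: Cohort, spec: POModelSpec):
    df = cohort.data.sort_values(["subject_id", "visit_index"], kind="stable")
    y_col = df[spec.response]
    if y_col.isna().any():
        raise ValueError(f"missing {spec.response} values; impute before fitting")
    y = y_col.to_numpy(int)
    X = build_design(df, tuple(spec.covariates))
    codes, _ = pd.factorize(df["subject_id"], sort=False)
    starts = np.flatnonzero(np.r_[1, np.diff(codes)])
    return X, y, codes, starts, df.index.to_numpy()


class _POPosterior:
    """Unconstrained log posterior of the proportional-odds model.

    Layout: beta (p), alpha_1, log-increments (K-2), [log sigma_b].
    """

    def __init__(self, cohort: Cohort, spec: POModelSpec):
        self.spec = spec
        self.K = spec.n_categories
        self.X, self.y, self.subj, self.starts, self.row_order = _po_arrays(cohort, spec)
        self.n_subjects = len(self.starts)
        self.p = self.X.shape[1]
        self.re = spec.include_random_effects
        self.ndim = self.p + (self.K - 1) + (1 if self.re else 0)
        if self.re:
            self.z, self.w = _gauss_hermite(spec.n_quad)
        else:
            self.z, self.w = np.zeros(1), np.ones(1)
        self.logw = np.log(self.w)
        self.param_names = (
            [f"beta_{c}" for c in spec.covariates]
            + [f"alpha_{k}" for k in range(1, self.K)]
            + (["sigma_b"] if self.re else [])
        )

    def _unpack(self, th: np.ndarray):
        p, K = self.p, self.K
        beta = th[:, :p]
        a1 = th[:, p]
        logd = th[:, p + 1 : p + K - 1]
        alpha = np.concatenate(
            [a1[:, None], a1[:, None] + np.cumsum(np.exp(logd), axis=1)], axis=1
        )
        sigma = np.exp(th[:, -1]) if self.re else np.zeros(len(th))
        return beta, alpha, logd, sigma

    def logp(self, th: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(np.asarray(th, float))
        B = th.shape[0]
        beta, alpha, logd, sigma = self._unpack(th)
        s = self.spec
        prior = (
            -0.5 * (beta**2).sum(axis=1) / s.prior_beta_sd**2
            - 0.5 * (alpha**2).sum(axis=1) / s.prior_alpha_sd**2
            + logd.sum(axis=1)
        )
        if self.re:
            prior += -0.5 * sigma**2 / s.prior_sigma_sd**2 + np.log(sigma)

        eta = self.X @ beta.T  # (R, B)
        inf = np.full((B, 1), np.inf)
        apad = np.concatenate([-inf, alpha, inf], axis=1)  # (B, K+1)
        hi = apad[:, self.y + 1].T - eta  # (R, B)
        lo = apad[:, self.y].T - eta
        Q = len(self.z)
        shift = (self.z[:, None] * sigma[None, :])[None, :, :]  # (1, Q, B)
        lp = _ordinal_logprob(hi[:, None, :] - shift, lo[:, None, :] - shift)  # (R, Q, B)
        subj_ll = np.add.reduceat(lp.reshape(len(self.y), Q * B), self.starts, axis=0)
        subj_ll = subj_ll.reshape(self.n_subjects, Q, B)
        like = logsumexp(subj_ll + self.logw[None, :, None], axis=1).sum(axis=0)
        out = prior + like
        return np.where(np.isfinite(out), out, -np.inf)

    def constrain(self, th: np.ndarray) -> np.ndarray:
        beta, alpha, _, sigma = self._unpack(np.atleast_2d(th))
        cols = [beta, alpha] + ([sigma[:, None]] if self.re else [])
        return np.concatenate(cols, axis=1)

    def initial_point(self) -> np.ndarray:
        counts = np.bincount(self.y, minlength=self.K).astype(float) + 0.5
        cum = np.clip(np.cumsum(counts)[:-1] / counts.sum(), 1e-4, 1 - 1e-4)
        alpha0 = np.log(cum / (1 - cum))
        d = np.maximum(np.diff(alpha0), 1e-2)
        x = np.concatenate(
            [np.zeros(self.p), [alpha0[0]], np.log(d)]
            + ([[np.log(0.5)]] if self.re else [])
        )
        return x


def fit_proportional_odds(
    cohorts, spec: POModelSpec, seed: int
) -> PosteriorDraws:
    """Fit the model on each completed cohort and pool the posteriors.

    ``cohorts`` is one Cohort or a list of M imputed Cohorts; each fit runs
    ``spec.mcmc.n_chains`` ensembles, is BGR/MCSE-checked (auto-extended up to
    ``max_extensions``) and the per-imputation posteriors are pooled by
    concatenating draws.
    """
    if isinstance(cohorts, Cohort):
        cohorts = [cohorts]
    fits = []
    for m, cohort in enumerate(cohorts):
        model = _POPosterior(cohort, spec)
        draws, report = sample_posterior(model, spec.mcmc, seed=(int(seed) + 7919 * m) % 2**31)
        draws.diagnostics = [report]
        fits.append(draws)
    return PosteriorDraws.pool(fits)


@dataclass
class ORTable:
    """Odds-ratio surface (GH scale x OH indicator) with 95% credible bounds."""

    table: pd.DataFrame  # columns: scale, effect, or_median, ci_low, ci_high

    def to_csv(self, path) -> str:
        self.table.to_csv(path, index=False, float_format="%.4f")
        return str(path)

    @classmethod
    def from_fits(cls, fits: dict, indicators=OH_INDICATORS) -> "ORTable":
        """Assemble the 4-scale x 3-indicator table from per-scale fits."""
        parts = [summarize_or(draws, indicators, scale).table for scale, draws in fits.items()]
        return cls(pd.concat(parts, ignore_index=True))


def summarize_or(
    draws: PosteriorDraws, indicators=OH_INDICATORS, scale: str = ""
) -> ORTable:
    """Posterior-median odds ratios and central 95% intervals, OR = exp(beta)."""
    rows = []
    for ind in indicators:
        b = draws.pooled(f"beta_{ind}")
        orr = np.exp(b)
        lo, med, hi = np.quantile(orr, [0.025, 0.5, 0.975])
        rows.append((scale, ind, float(med), float(lo), float(hi)))
    return ORTable(
        pd.DataFrame(rows, columns=["scale", "effect", "or_median", "ci_low", "ci_high"])
    )


def posterior_predict_categories(
    draws: PosteriorDraws,
    cohort: Cohort,
    spec: POModelSpec,
    seed: int,
    n_draws: int = 200,
) -> np.ndarray:
    """Posterior-median predicted category per record (lower median on ties).

    For each retained posterior draw the subject intercept is re-drawn from
    its conditional posterior given that subject's responses (discretized on
    the quadrature grid), a response category is sampled, and the per-record
    median over draws is returned (aligned with ``cohort.data`` rows sorted by
    subject and visit).
    """
    model = _POPosterior(cohort, spec)
    rng = np.random.default_rng(int(seed) % 2**31)
    flat = draws.array.reshape(-1, len(draws.names))
    take = np.linspace(0, len(flat) - 1, min(n_draws, len(flat))).astype(int)
    names = list(draws.names)
    bidx = [names.index(f"beta_{c}") for c in spec.covariates]
    aidx = [names.index(f"alpha_{k}") for k in range(1, model.K)]
    sidx = names.index("sigma_b") if model.re else None

    R = len(model.y)
    apad_inf = np.inf
    preds = np.empty((R, len(take)), dtype=np.int16)
    for col, s in enumerate(take):
        beta = flat[s, bidx]
        alpha = flat[s, aidx]
        sigma = flat[s, sidx] if model.re else 0.0
        eta = model.X @ beta
        apad = np.concatenate([[-apad_inf], alpha, [apad_inf]])
        if model.re and sigma > 0:
            shifts = sigma * model.z  # (Q,)
            lp = _ordinal_logprob(
                (apad[model.y + 1] - eta)[:, None] - shifts[None, :],
                (apad[model.y] - eta)[:, None] - shifts[None, :],
            )  # (R, Q)
            subj_ll = np.add.reduceat(lp, model.starts, axis=0) + model.logw[None, :]
            subj_ll -= subj_ll.max(axis=1, keepdims=True)
            wts = np.exp(subj_ll)
            wts /= wts.sum(axis=1, keepdims=True)
            picks = (rng.uniform(size=len(wts))[:, None] > np.cumsum(wts, axis=1)).sum(axis=1)
            b = shifts[np.minimum(picks, len(shifts) - 1)][model.subj]
        else:
            b = 0.0
        cum = expit(alpha[None, :] - (eta + b)[:, None])
        preds[:, col] = (rng.uniform(size=R)[:, None] > cum).sum(axis=1)
    preds.sort(axis=1)
    med = preds[:, (preds.shape[1] - 1) // 2].astype(int)
    out = np.empty(R, dtype=int)
    out[model.row_order] = med  # back to the cohort's original row order
    return out
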