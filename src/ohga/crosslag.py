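"""Bivariate ordinal autoregressive (cross-lagged) model — second analysis.

For one (GH scale, OH indicator) pair the responses at visit j >= 2 are
modeled jointly, with the observed values at the previous examination as
regressors:

    GH equation (cumulative logit):
        P(GH_ij <= k) = logistic(alpha_k - eta1),
        eta1 = gamma11*GH_{i,j-1} + gamma12*OH_{i,j-1} + x' delta1 + u_i1
    OH equation (logit):
        P(OH_ij = 1) = logistic(c2 + gamma21*GH_{i,j-1} + gamma22*OH_{i,j-1}
                                + x' delta2 + u_i2)

with (u_i1, u_i2) bivariate normal (SDs s1, s2, correlation r) as the
cross-equation coupling.  gamma12 is the cross-lagged effect of oral health on
future general health and gamma21 the reverse; the lagged GH score enters as
its integer value.  Visit-1 responses are conditioned on, never modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_expit, logsumexp

from .cohort import Cohort
from .design import VAR_COVARIATES, build_design
from .diagnostics import MCMCConfig
from .propodds import _gauss_hermite, _ordinal_logprob
from .sampling import PosteriorDraws, sample_posterior
from .scales import GH_SCALES, OH_INDICATORS, SCALES

try:
    from . import _kernels as _kernel
except ImportError:  # numba unavailable: numpy path only
    _kernel = None

__all__ = [
    "VARPairSpec",
    "CrossLagEstimates",
    "CrossLagGraph",
    "build_transition_frame",
    "fit_bivariate_var",
    "summarize_crosslag",
    "assemble_graph",
]

GAMMA_NAMES = ("gamma11", "gamma12", "gamma21", "gamma22")


@dataclass
class VARPairSpec:
    """One (GH, OH) pair of the second analysis."""

    gh: str = "ADL"
    oh: str = "CD"
    covariates: tuple = VAR_COVARIATES
    include_random_effects: bool = True
    n_quad: int = 7
    prior_coef_sd: float = 10.0
    prior_alpha_sd: float = 10.0
    prior_sigma_sd: float = 5.0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if self.gh not in GH_SCALES:
            raise ValueError(f"gh must be one of {GH_SCALES}")
        if self.oh not in OH_INDICATORS:
            raise ValueError(f"oh must be a binary OH indicator, got {self.oh!r}")

    @property
    def n_categories(self) -> int:
        return SCALES[self.gh].n_categories


def build_transition_frame(cohort: Cohort, pair: VARPairSpec) -> pd.DataFrame:
    """Lagged design set: one row per visit j >= 2.

    Columns: the pair's current responses, their previous-visit values
    (``*_lag``), the current-visit covariate source columns and
    ``subject_id``.  Single-visit subjects contribute nothing.
    """
    df = cohort.data.sort_values(["subject_id", "visit_index"], kind="stable")
    need = [pair.gh, pair.oh]
    if df[need].isna().any().any():
        raise ValueError(f"missing {pair.gh}/{pair.oh} values; impute before lagging")
    same = df["subject_id"] == df["subject_id"].shift(1)
    consecutive = df["visit_index"] == df["visit_index"].shift(1) + 1
    keep = (same & consecutive).to_numpy()
    out = df.loc[keep].copy()
    out[f"{pair.gh}_lag"] = df[pair.gh].shift(1).loc[keep].astype(int)
    out[f"{pair.oh}_lag"] = df[pair.oh].shift(1).loc[keep].astype(int)
    return out.reset_index(drop=True)


class _VARPosterior:
    """Unconstrained log posterior of the bivariate cross-lagged model.

    Layout: alpha_1, log-increments (K-2), gamma11, gamma12, delta1 (c),
    c2, gamma21, gamma22, delta2 (c), [log s1, log s2, atanh r].
    """

    def __init__(self, frame: pd.DataFrame, pair: VARPairSpec):
        if len(frame) == 0:
            raise ValueError("empty transition frame: no subject has >= 2 visits")
        self.pair = pair
        self.K = pair.n_categories
        self.y1 = frame[pair.gh].to_numpy(int)
        self.y2 = frame[pair.oh].to_numpy(int)
        self.lag1 = frame[f"{pair.gh}_lag"].to_numpy(float)
        self.lag2 = frame[f"{pair.oh}_lag"].to_numpy(float)
        self.Xc = build_design(frame, tuple(pair.covariates))
        self.c = self.Xc.shape[1]
        codes, _ = pd.factorize(frame["subject_id"], sort=False)
        self.starts = np.flatnonzero(np.r_[1, np.diff(codes)])
        self.n_subjects = len(self.starts)
        self.re = pair.include_random_effects
        self.ndim = (self.K - 1) + 3 + 2 * self.c + 2 + (3 if self.re else 0)
        self.z, self.w = _gauss_hermite(pair.n_quad if self.re else 1)
        if not self.re:
            self.z, self.w = np.zeros(1), np.ones(1)
        self.logw = np.log(self.w)
        cov1 = [f"delta1_{c}" for c in pair.covariates]
        cov2 = [f"delta2_{c}" for c in pair.covariates]
        self.param_names = (
            [f"alpha_{k}" for k in range(1, self.K)]
            + ["gamma11", "gamma12"] + cov1
            + ["c2", "gamma21", "gamma22"] + cov2
            + (["sd_u1", "sd_u2", "r_u"] if self.re else [])
        )

    def _unpack(self, th: np.ndarray):
        K, c = self.K, self.c
        i = 0
        a1 = th[:, i]
        logd = th[:, i + 1 : i + K - 1]
        alpha = np.concatenate(
            [a1[:, None], a1[:, None] + np.cumsum(np.exp(logd), axis=1)], axis=1
        )
        i += K - 1
        g11, g12 = th[:, i], th[:, i + 1]
        d1 = th[:, i + 2 : i + 2 + c]
        i += 2 + c
        c2, g21, g22 = th[:, i], th[:, i + 1], th[:, i + 2]
        d2 = th[:, i + 3 : i + 3 + c]
        i += 3 + c
        if self.re:
            s1, s2 = np.exp(th[:, i]), np.exp(th[:, i + 1])
            r = np.tanh(th[:, i + 2])
        else:
            s1 = s2 = r = np.zeros(len(th))
        return alpha, logd, g11, g12, d1, c2, g21, g22, d2, s1, s2, r

    def _log_prior(self, th: np.ndarray):
        alpha, logd, g11, g12, d1, c2, g21, g22, d2, s1, s2, r = self._unpack(th)
        sp = self.pair
        coef_sq = (
            g11**2 + g12**2 + g21**2 + g22**2 + c2**2
            + (d1**2).sum(axis=1) + (d2**2).sum(axis=1)
        )
        prior = (
            -0.5 * coef_sq / sp.prior_coef_sd**2
            - 0.5 * (alpha**2).sum(axis=1) / sp.prior_alpha_sd**2
            + logd.sum(axis=1)
        )
        if self.re:
            prior += (
                -0.5 * (s1**2 + s2**2) / sp.prior_sigma_sd**2
                + np.log(s1) + np.log(s2)
                + np.log1p(-r**2)
            )
        return prior

    def logp(self, th: np.ndarray) -> np.ndarray:
        """Log posterior; compiled kernel when available, else the numpy path."""
        th = np.atleast_2d(np.asarray(th, float))
        if self.re and _kernel is not None:
            alpha, _, g11, g12, d1, c2, g21, g22, d2, s1, s2, r = self._unpack(th)
            like = _kernel.var_loglik(
                self.y1, self.y2, self.lag1, self.lag2,
                np.ascontiguousarray(self.Xc @ d1.T), np.ascontiguousarray(self.Xc @ d2.T),
                self.starts, np.ascontiguousarray(alpha),
                np.ascontiguousarray(g11), np.ascontiguousarray(g12),
                np.ascontiguousarray(g21), np.ascontiguousarray(g22),
                np.ascontiguousarray(c2), np.ascontiguousarray(s1),
                np.ascontiguousarray(s2), np.ascontiguousarray(r),
                self.z, self.logw,
            )
            out = self._log_prior(th) + like
            return np.where(np.isfinite(out), out, -np.inf)
        return self.logp_reference(th)

    def logp_reference(self, th: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(np.asarray(th, float))
        B = th.shape[0]
        alpha, logd, g11, g12, d1, c2, g21, g22, d2, s1, s2, r = self._unpack(th)
        prior = self._log_prior(th)

        eta1 = (
            self.lag1[:, None] * g11[None, :]
            + self.lag2[:, None] * g12[None, :]
            + self.Xc @ d1.T
        )  # (R, B)
        eta2 = (
            c2[None, :]
            + self.lag1[:, None] * g21[None, :]
            + self.lag2[:, None] * g22[None, :]
            + self.Xc @ d2.T
        )
        inf = np.full((B, 1), np.inf)
        apad = np.concatenate([-inf, alpha, inf], axis=1)
        hi = apad[:, self.y1 + 1].T - eta1
        lo = apad[:, self.y1].T - eta1
        sgn = (2 * self.y2 - 1).astype(float)

        Q, S, R = len(self.z), self.n_subjects, len(self.y1)
        rt = np.sqrt(np.clip(1.0 - r**2, 0.0, None))
        u1 = (self.z[:, None] * s1[None, :])[None, :, :]  # (1, Q, B)
        glp = _ordinal_logprob(hi[:, None, :] - u1, lo[:, None, :] - u1)  # (R, Q, B)
        G = np.add.reduceat(glp.reshape(R, Q * B), self.starts, axis=0).reshape(S, Q, B)
        # u2 over the (q1, q2) grid: s2 * (r z_q1 + sqrt(1-r^2) z_q2)
        u2 = s2 * (r * self.z[:, None, None] + rt * self.z[None, :, None])  # (Q, Q, B)
        arg = sgn[:, None, None] * (eta2[:, None, :] + u2.reshape(Q * Q, B)[None, :, :])
        O = np.add.reduceat(log_expit(arg).reshape(R, Q * Q * B), self.starts, axis=0)
        O = O.reshape(S, Q, Q, B)

        total = (
            G[:, :, None, :]
            + O
            + self.logw[None, :, None, None]
            + self.logw[None, None, :, None]
        )  # (S, Q, Q, B)
        like = logsumexp(total.reshape(S, Q * Q, B), axis=1).sum(axis=0)
        out = prior + like
        return np.where(np.isfinite(out), out, -np.inf)

    def constrain(self, th: np.ndarray) -> np.ndarray:
        alpha, _, g11, g12, d1, c2, g21, g22, d2, s1, s2, r = self._unpack(np.atleast_2d(th))
        cols = [alpha, g11[:, None], g12[:, None], d1, c2[:, None], g21[:, None],
                g22[:, None], d2]
        if self.re:
            cols += [s1[:, None], s2[:, None], r[:, None]]
        return np.concatenate(cols, axis=1)

    def initial_point(self) -> np.ndarray:
        counts = np.bincount(self.y1, minlength=self.K).astype(float) + 0.5
        cum = np.clip(np.cumsum(counts)[:-1] / counts.sum(), 1e-4, 1 - 1e-4)
        alpha0 = np.log(cum / (1 - cum))
        d = np.maximum(np.diff(alpha0), 1e-2)
        p2 = np.clip(self.y2.mean(), 0.02, 0.98)
        x = np.concatenate(
            [[alpha0[0]], np.log(d), np.zeros(2 + self.c),
             [np.log(p2 / (1 - p2))], np.zeros(2 + self.c)]
            + ([[np.log(0.5), np.log(0.5), 0.0]] if self.re else [])
        )
        return x


def fit_bivariate_var(frames, pair: VARPairSpec, seed: int) -> PosteriorDraws:
    """Fit the pair model on each imputation's transition frame and pool.

    ``frames`` is one DataFrame from :func:`build_transition_frame` or a list
    of M of them.
    """
    if isinstance(frames, pd.DataFrame):
        frames = [frames]
    fits = []
    for m, frame in enumerate(frames):
        model = _VARPosterior(frame, pair)
        draws, report = sample_posterior(model, pair.mcmc, seed=(int(seed) + 104729 * m) % 2**31)
        draws.diagnostics = [report]
        fits.append(draws)
    return PosteriorDraws.pool(fits)


@dataclass
class CrossLagEstimates:
    """Posterior means and 95% intervals of the 2x2 lag-coefficient block."""

    gh: str
    oh: str
    estimates: dict  # gamma name -> (mean, ci_low, ci_high)
    significant: dict  # gamma name -> bool (interval excludes 0)
    r: tuple | None = None  # (mean, ci_low, ci_high) of the intercept correlation

    def __post_init__(self) -> None:
        for name, (mean, lo, hi) in self.estimates.items():
            if not lo <= hi:
                raise ValueError(f"{name}: interval bounds out of order")
            if self.significant[name] != (lo > 0 or hi < 0):
                raise ValueError(f"{name}: significance flag inconsistent with bounds")

    def to_dict(self) -> dict:
        return {
            "gh": self.gh,
            "oh": self.oh,
            "gammas": {
                k: {"mean": v[0], "ci_low": v[1], "ci_high": v[2],
                    "significant": self.significant[k]}
                for k, v in self.estimates.items()
            },
            "r": None if self.r is None else
                {"mean": self.r[0], "ci_low": self.r[1], "ci_high": self.r[2]},
        }


def summarize_crosslag(
    draws: PosteriorDraws, gh: str = "", oh: str = "", prob: float = 0.95
) -> CrossLagEstimates:
    """Posterior means / central intervals for gamma11..gamma22 (and r).

    A positive gamma12 reads: a worse OH state now is additionally predictive
    of a worse GH state at the next examination (and gamma21 the reverse).
    """
    est, sig = {}, {}
    for name in GAMMA_NAMES:
        pool = draws.pooled(name)
        lo, hi = draws.interval(name, prob)
        est[name] = (float(pool.mean()), lo, hi)
        sig[name] = lo > 0 or hi < 0
    r = None
    if "r_u" in draws.names:
        lo, hi = draws.interval("r_u", prob)
        r = (draws.mean("r_u"), lo, hi)
    return CrossLagEstimates(gh, oh, est, sig, r)


@dataclass
class CrossLagGraph:
    """Directed significant-cross-lag graph over the 7 indicators."""

    nodes: tuple
    edges: list  # dicts: source, target, sign, mean, ci_low, ci_high

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "edges": self.edges}


def assemble_graph(estimates: dict) -> CrossLagGraph:
    """Build the association graph from all 12 pair fits.

    ``estimates`` maps (gh, oh) -> CrossLagEstimates; an edge OH -> GH is
    present iff that pair's gamma12 interval excludes 0, and GH -> OH iff
    gamma21's does.
    """
    required = [(g, o) for g in GH_SCALES for o in OH_INDICATORS]
    missing = [p for p in required if p not in estimates]
    if missing:
        raise ValueError(f"missing pair estimates: {missing}")
    edges = []
    for (gh, oh) in required:
        e = estimates[(gh, oh)]
        for name, (src, dst) in (("gamma12", (oh, gh)), ("gamma21", (gh, oh))):
            mean, lo, hi = e.estimates[name]
            if e.significant[name]:
                edges.append(
                    {"source": src, "target": dst, "sign": 1 if mean > 0 else -1,
                     "mean": mean, "ci_low": lo, "ci_high": hi}
                )
    return CrossLagGraph(tuple(GH_SCALES) + tuple(OH_INDICATORS), edges)
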