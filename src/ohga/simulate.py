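"""Synthetic home-care registry generator.

Emulates a BelRAI-like longitudinal cohort: ~8,359 older adults assessed
roughly every six months (1-10 assessments each), with baseline covariates
drawn from the registry's published marginals and the seven OH/GH indicators
evolving under the same statistical structure the two analysis models assume:

* each GH scale follows a cumulative-logit (proportional-odds) process with a
  normal subject intercept, current-visit OH effects and an own-lag term;
* each OH item follows a logistic autoregression with a subject intercept;
* one (GH, OH) focal pair may carry cross-lagged couplings (gamma12: lagged
  OH in the GH equation; gamma21: lagged GH in the OH equation) and a
  correlation between the pair's subject intercepts.

The generator produces fully observed cohorts; missingness is a separate
masking stage (:mod:`ohga.missingness`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .cohort import Cohort, COLUMNS
from .design import PO_COVARIATES, build_design
from .scales import GH_SCALES, OH_INDICATORS, SCALES, INTERVENTIONS

__all__ = [
    "TrueParams",
    "GeneratorConfig",
    "calibrate_visit_pmf",
    "simulate_cohort",
]


class CalibrationError(ValueError):
    """Visit-count targets cannot be met on the supported range."""


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# visit-count distribution
# ---------------------------------------------------------------------------

def calibrate_visit_pmf(
    target_mean_visits: float = 13187.0 / 8359.0,
    target_mean_among_multi: float = 2.4,
    max_visits: int = 10,
) -> np.ndarray:
    """Probability vector over total visit counts 1..``max_visits``.

    Family: a point mass at one visit mixed with a truncated geometric on
    2..``max_visits``; the two free parameters (mixture weight, geometric
    rate) are solved so that the overall mean number of visits per subject
    and the mean among subjects with at least two visits match the targets
    (the registry's 13187/8359 ~ 1.578 and 2.4 respectively).
    """
    k = np.arange(1, max_visits + 1)
    if target_mean_visits < 1 or target_mean_visits > max_visits:
        raise CalibrationError(f"overall mean {target_mean_visits} outside [1, {max_visits}]")
    if abs(target_mean_visits - 1.0) < 1e-12:
        pmf = np.zeros(max_visits)
        pmf[0] = 1.0
        return pmf

    def multi_pmf(q: float) -> np.ndarray:
        g = (1 - q) ** (k[1:] - 2) * q  # geometric shape on 2..max
        return g / g.sum()

    def cond_mean_multi(q: float) -> float:
        return float((k[1:] * multi_pmf(q)).sum())

    lo_mean, hi_mean = cond_mean_multi(1 - 1e-9), cond_mean_multi(1e-9)
    if not (lo_mean - 1e-6 <= target_mean_among_multi <= hi_mean + 1e-6):
        raise CalibrationError(
            f"mean among multi-visit subjects {target_mean_among_multi} outside "
            f"achievable range [{lo_mean:.3f}, {hi_mean:.3f}]"
        )
    # overall mean = P(N=1) + P(N>=2) * cond_mean -> solve P(N>=2)
    p_multi = (target_mean_visits - 1.0) / (target_mean_among_multi - 1.0)
    if not 0.0 <= p_multi <= 1.0:
        raise CalibrationError(
            f"required P(>=2 visits)={p_multi:.4f} outside [0,1]: targets "
            f"(mean {target_mean_visits}, mean among multi {target_mean_among_multi}) "
            "are inconsistent"
        )
    if target_mean_among_multi <= lo_mean:
        q = 1 - 1e-9
    elif target_mean_among_multi >= hi_mean:
        q = 1e-9
    else:
        q = optimize.brentq(
            lambda x: cond_mean_multi(x) - target_mean_among_multi, 1e-9, 1 - 1e-9,
            xtol=1e-12,
        )
    pmf = np.concatenate([[1.0 - p_multi], p_multi * multi_pmf(q)])
    pmf /= pmf.sum()
    mean = float((k * pmf).sum())
    if abs(mean - target_mean_visits) > 1e-3:
        raise CalibrationError(f"calibration achieved mean {mean}, target {target_mean_visits}")
    return pmf


# ---------------------------------------------------------------------------
# true parameters
# ---------------------------------------------------------------------------

def _alpha_from_pmf(pmf) -> np.ndarray:
    cum = np.cumsum(np.asarray(pmf, float))[:-1]
    return logit(np.clip(cum, 1e-6, 1 - 1e-6))


# marginal category pmfs at linear predictor zero; ADL's taken from the
# observed marginal of the published 7x7 contingency table, others chosen as
# realistic skewed-to-healthy shapes.
_DEFAULT_GH_PMF = {
    "ADL": np.array([3417, 1054, 2221, 3066, 1430, 920, 216], float) / 12324.0,
    "CPS": np.array([0.35, 0.20, 0.15, 0.12, 0.08, 0.06, 0.04]),
    "DRS": 0.7 ** np.arange(15) * 0.3 / (1 - 0.7**15),
    "CHESS": np.array([0.45, 0.25, 0.15, 0.08, 0.045, 0.025]),
}

#: odds ratios of each OH item per GH scale used as default current-visit effects
_DEFAULT_OH_OR = {
    "ADL": {"NT": 1.195, "CD": 3.452, "DM": 1.390},
    "CPS": {"NT": 2.378, "CD": 10.886, "DM": 0.967},
    "DRS": {"NT": 1.709, "CD": 3.729, "DM": 3.711},
    "CHESS": {"NT": 1.287, "CD": 3.102, "DM": 2.686},
}

_DEFAULT_COVARIATE_BETA = {
    "age_c": 0.4,
    "female": -0.1,
    "int_night_care": 0.2,
    "int_occupational_therapy": 0.1,
    "int_other": 0.15,
    "time": 0.1,
    "int_night_care:time": 0.0,
    "int_occupational_therapy:time": 0.0,
    "int_other:time": 0.0,
    "living_alone": -0.2,
    "informal_caregiver": 0.3,
}

_DEFAULT_OH_PREVALENCE = {"NT": 0.45, "CD": 0.30, "DM": 0.25}


@dataclass
class TrueParams:
    """Generator truths on the latent logit scale.

    ``beta[gh][cov]`` are cumulative-logit fixed effects (positive = worse GH);
    ``alpha[gh]`` strictly increasing thresholds; ``ar_gh``/``ar_oh`` own-lag
    coefficients (gamma11 / gamma22); ``crosslag[(gh, oh)] = (gamma12,
    gamma21)``; ``re_corr[(gh, oh)]`` the correlation between the pair's
    subject intercepts; ``sigma_*`` random-intercept SDs.
    """

    beta: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)
    oh_intercept: dict = field(default_factory=dict)
    ar_gh: dict = field(default_factory=dict)
    ar_oh: dict = field(default_factory=dict)
    crosslag: dict = field(default_factory=dict)
    sigma_gh: dict = field(default_factory=dict)
    sigma_oh: dict = field(default_factory=dict)
    re_corr: dict = field(default_factory=dict)
    init_mode: str = "midpoint"  # lag stand-in at visit 1: "midpoint" | "uniform"
    # Whether visit-1 states include the subject intercepts.  True is the
    # realistic default; False makes first visits independent of the random
    # effects, so a model that conditions on visit-1 values (the cross-lagged
    # analysis) is exactly the conditional law of later visits and parameter
    # recovery is free of the dynamic-panel initial-conditions problem.
    init_include_re: bool = True

    def __post_init__(self) -> None:
        for gh in GH_SCALES:
            self.alpha.setdefault(gh, _alpha_from_pmf(_DEFAULT_GH_PMF[gh]))
            b = dict(_DEFAULT_COVARIATE_BETA)
            b.update({oh: math.log(v) for oh, v in _DEFAULT_OH_OR[gh].items()})
            self.beta.setdefault(gh, b)
            self.ar_gh.setdefault(gh, 0.25)
            self.sigma_gh.setdefault(gh, 1.0)
        for oh in OH_INDICATORS:
            prev = _DEFAULT_OH_PREVALENCE[oh]
            self.oh_intercept.setdefault(oh, float(logit(prev)) - 0.8 * prev)
            self.ar_oh.setdefault(oh, 0.8)
            self.sigma_oh.setdefault(oh, 0.8)
        if not self.crosslag and not self.re_corr:
            self.crosslag = {("ADL", "CD"): (0.077, 0.031)}
            self.re_corr = {("ADL", "CD"): 0.3}
        self.validate()

    def validate(self) -> None:
        for gh, a in self.alpha.items():
            a = np.asarray(a, float)
            if len(a) != SCALES[gh].n_categories - 1 or not np.all(np.diff(a) > 0):
                raise ConfigError(f"alpha[{gh}] must be strictly increasing, length K-1")
            self.alpha[gh] = a
        for d in (self.sigma_gh, self.sigma_oh):
            if any(v < 0 for v in d.values()):
                raise ConfigError("random-intercept SDs must be >= 0")
        if any(not -1 < r < 1 for r in self.re_corr.values()):
            raise ConfigError("|random-effect correlation| must be < 1")

    # -- factories ----------------------------------------------------------
    @classmethod
    def default(cls) -> "TrueParams":
        return cls()

    @classmethod
    def for_proportional_odds(cls, beta_overrides: dict | None = None) -> "TrueParams":
        """No lag dynamics: each GH scale is the proportional-odds model exactly."""
        p = cls(
            ar_gh={g: 0.0 for g in GH_SCALES},
            ar_oh={o: 0.0 for o in OH_INDICATORS},
            crosslag={},
            re_corr={},
        )
        p.crosslag, p.re_corr = {}, {}
        if beta_overrides:
            for gh, d in beta_overrides.items():
                p.beta[gh].update(d)
        return p

    @classmethod
    def for_crosslag(
        cls,
        gh: str = "ADL",
        oh: str = "CD",
        gamma11: float = 0.25,
        gamma12: float = 0.077,
        gamma21: float = 0.031,
        gamma22: float = 0.8,
        r: float = 0.3,
    ) -> "TrueParams":
        """Pure bivariate autoregression on one focal pair (no covariate effects)."""
        p = cls(
            beta={g: {c: 0.0 for c in list(PO_COVARIATES)} for g in GH_SCALES},
            crosslag={(gh, oh): (gamma12, gamma21)},
            re_corr={(gh, oh): r},
            init_include_re=False,
        )
        p.ar_gh = {g: 0.0 for g in GH_SCALES}
        p.ar_oh = {o: 0.0 for o in OH_INDICATORS}
        p.ar_gh[gh] = gamma11
        p.ar_oh[oh] = gamma22
        return p

    @classmethod
    def null(cls) -> "TrueParams":
        """All covariate, lag and cross-lag effects zero (intercept-only)."""
        p = cls.for_crosslag(gamma11=0.0, gamma12=0.0, gamma21=0.0, gamma22=0.0, r=0.0)
        p.crosslag, p.re_corr = {}, {}
        return p


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

_RAW_INTERVENTION = np.array([0.5943, 0.1643, 0.1095, 0.0929])


@dataclass
class GeneratorConfig:
    """Study conditions of the emulated registry (defaults = published values)."""

    n_subjects: int = 8359
    seed: int = 0
    age_mean: float = 81.2
    age_sd: float = 7.0
    age_range: tuple = (65.0, 102.0)
    p_female: float = 0.683
    # published shares sum to 96.10%; renormalized to a proper 4-vector
    intervention_probs: tuple = tuple(_RAW_INTERVENTION / _RAW_INTERVENTION.sum())
    p_living_alone: float = 0.55
    p_informal_caregiver: float = 0.786
    covariate_switch_prob: float = 0.05
    visit_count_pmf: np.ndarray | None = None
    fixed_n_visits: int | None = None  # overrides the pmf when set
    true_params: TrueParams = field(default_factory=TrueParams)

    def __post_init__(self) -> None:
        if self.visit_count_pmf is None:
            self.visit_count_pmf = calibrate_visit_pmf()
        self.visit_count_pmf = np.asarray(self.visit_count_pmf, float)
        if abs(self.visit_count_pmf.sum() - 1.0) > 1e-9 or (self.visit_count_pmf < 0).any():
            raise ConfigError("visit_count_pmf must be a probability vector (sum 1)")
        if abs(sum(self.intervention_probs) - 1.0) > 1e-9:
            raise ConfigError("intervention_probs must sum to 1")
        for name in ("p_female", "p_living_alone", "p_informal_caregiver"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")


def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter for which the [lo,hi]-truncated normal has the given mean."""

    def tmean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    return optimize.brentq(lambda m: tmean(m) - mean, lo, hi, xtol=1e-10)


def _markov_rates(p: float, switch: float) -> tuple[float, float]:
    """(0->1, 1->0) rates with stationary P(1)=p and expected switch prob ``switch``."""
    if p <= 0.0 or p >= 1.0:
        return 0.0, 0.0
    c = min(switch / (2 * p * (1 - p)), 1.0 / max(p, 1 - p))
    return c * p, c * (1 - p)


def _re_covariance(params: TrueParams) -> tuple[list[str], np.ndarray]:
    names = list(GH_SCALES) + list(OH_INDICATORS)
    sd = np.array([params.sigma_gh[g] for g in GH_SCALES] + [params.sigma_oh[o] for o in OH_INDICATORS])
    corr = np.eye(len(names))
    for (gh, oh), r in params.re_corr.items():
        i, j = names.index(gh), names.index(oh)
        corr[i, j] = corr[j, i] = r
    cov = corr * np.outer(sd, sd)
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ConfigError("random-effect correlation structure is not positive semidefinite")
    return names, cov


def _draw_cumlogit(rng, eta: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw ordinal categories: P(Y<=k) = expit(alpha_k - eta)."""
    cum = expit(alpha[None, :] - eta[:, None])  # (n, K-1)
    u = rng.uniform(size=len(eta))
    return (u[:, None] > cum).sum(axis=1)


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a fully observed cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    p = config.true_params
    lo, hi = config.age_range

    loc = _truncnorm_loc(config.age_mean, config.age_sd, lo, hi)
    a, b = (lo - loc) / config.age_sd, (hi - loc) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=config.age_sd, size=n, random_state=rng)
    female = rng.uniform(size=n) < config.p_female
    intervention = rng.choice(INTERVENTIONS, size=n, p=np.asarray(config.intervention_probs))
    if config.fixed_n_visits is not None:
        n_visits = np.full(n, config.fixed_n_visits)
    else:
        n_visits = rng.choice(
            np.arange(1, len(config.visit_count_pmf) + 1), size=n, p=config.visit_count_pmf
        )
    max_visits = int(n_visits.max())
    first_date = np.datetime64("2012-01-01") + rng.integers(0, 1096, size=n)

    re_names, re_cov = _re_covariance(p)
    re_draws = rng.multivariate_normal(np.zeros(len(re_names)), re_cov, size=n)
    re_by = {name: re_draws[:, i] for i, name in enumerate(re_names)}

    # focal couplings: for each GH (resp OH) at most one partner drives a cross-lag
    gh_partner = {gh: oh for (gh, oh) in p.crosslag}
    oh_partner = {oh: gh for (gh, oh) in p.crosslag}

    alive = np.ones(n, bool)
    living = rng.uniform(size=n) < config.p_living_alone
    caregiver = rng.uniform(size=n) < config.p_informal_caregiver
    la01, la10 = _markov_rates(config.p_living_alone, config.covariate_switch_prob)
    cg01, cg10 = _markov_rates(config.p_informal_caregiver, config.covariate_switch_prob)

    gh_prev = {g: np.zeros(n) for g in GH_SCALES}
    oh_prev = {o: np.zeros(n) for o in OH_INDICATORS}
    dates = first_date.copy()
    rows: list[pd.DataFrame] = []

    for t in range(1, max_visits + 1):
        alive = n_visits >= t
        idx = np.flatnonzero(alive)
        if t > 1:
            gaps = rng.integers(153, 214, size=n)  # days; 5..7 months inclusive
            dates = dates + gaps
            flip = rng.uniform(size=n)
            living = np.where(living, flip >= la10, flip < la01)
            flip = rng.uniform(size=n)
            caregiver = np.where(caregiver, flip >= cg10, flip < cg01)

        if t == 1:
            if p.init_mode == "uniform":
                lag_gh = {g: rng.integers(0, SCALES[g].n_categories, size=n).astype(float) for g in GH_SCALES}
                lag_oh = {o: rng.integers(0, 2, size=n).astype(float) for o in OH_INDICATORS}
            else:  # category-midpoint expectations
                lag_gh = {g: np.full(n, SCALES[g].max_code / 2.0) for g in GH_SCALES}
                lag_oh = {o: np.full(n, 0.5) for o in OH_INDICATORS}
        else:
            lag_gh = {g: gh_prev[g].astype(float) for g in GH_SCALES}
            lag_oh = {o: oh_prev[o].astype(float) for o in OH_INDICATORS}

        re_on = 1.0 if (t > 1 or p.init_include_re) else 0.0
        oh_now: dict[str, np.ndarray] = {}
        for o in OH_INDICATORS:
            eta = p.oh_intercept[o] + p.ar_oh[o] * lag_oh[o] + re_on * re_by[o]
            if o in oh_partner:
                g21 = p.crosslag[(oh_partner[o], o)][1]
                eta = eta + g21 * lag_gh[oh_partner[o]]
            oh_now[o] = (rng.uniform(size=n) < expit(eta)).astype(int)

        frame = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "visit_index": t,
                "age_baseline": age,
                "gender": np.where(female, "female", "male"),
                "intervention": intervention,
                "living_alone": living.astype(int),
                "informal_caregiver": caregiver.astype(int),
                **{o: oh_now[o] for o in OH_INDICATORS},
            }
        )
        gh_now: dict[str, np.ndarray] = {}
        for g in GH_SCALES:
            covs = tuple(p.beta[g].keys())
            X = build_design(frame, covs)
            beta = np.array([p.beta[g][c] for c in covs])
            eta = X @ beta + p.ar_gh[g] * lag_gh[g] + re_on * re_by[g]
            if g in gh_partner:
                g12 = p.crosslag[(g, gh_partner[g])][0]
                eta = eta + g12 * lag_oh[gh_partner[g]]
            gh_now[g] = _draw_cumlogit(rng, eta, p.alpha[g])

        visit = pd.DataFrame(
            {
                "subject_id": [f"S{j:06d}" for j in idx],
                "visit_index": t,
                "assessment_date": pd.to_datetime(dates[idx]),
                "age_baseline": age[idx],
                "gender": np.where(female[idx], "female", "male"),
                "intervention": intervention[idx],
                "living_alone": living[idx].astype(int),
                "informal_caregiver": caregiver[idx].astype(int),
                **{o: oh_now[o][idx] for o in OH_INDICATORS},
                **{g: gh_now[g][idx] for g in GH_SCALES},
            }
        )
        rows.append(visit)
        for g in GH_SCALES:
            gh_prev[g] = gh_now[g]
        for o in OH_INDICATORS:
            oh_prev[o] = oh_now[o]

    df = pd.concat(rows, ignore_index=True)
    df = df.sort_values(["subject_id", "visit_index"], kind="stable").reset_index(drop=True)
    for name in GH_SCALES + OH_INDICATORS + ("living_alone", "informal_caregiver"):
        df[name] = df[name].astype("Int64")
    cohort = Cohort(df, provenance=f"synthetic seed={config.seed} n={n}")
    cohort.validate()
    return cohort
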