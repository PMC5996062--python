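"""MAR masking and sequential (chained) Bayesian imputation.

Masking reproduces the registry's missingness profile — roughly 5-7% on the
GH scales and the informal-caregiver flag, ~17% on the OH items and ~23% on
CHESS — with the missingness probability driven only by always-observed
covariates (age, gender, visit index), i.e. missing at random.

Imputation is a fully-conditional sequence ordered from least- to
most-missing variable: a Bayesian logistic model for each binary variable and
a cumulative-logit model for each ordinal one, each conditioning on all other
analysis variables.  Models are fit by posterior-mode + normal (Laplace)
approximation and each of the M completed datasets uses its own posterior
parameter draw, so between-imputation variability reflects parameter
uncertainty.  Pooling of downstream fits concatenates posterior draws
(mixture-of-posteriors pooling of fully Bayesian fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort
from .sampling import PosteriorDraws
from .scales import BINARY_COVARIATES, GH_SCALES, OH_INDICATORS

__all__ = [
    "MissingnessSpec",
    "ImputationModelSequence",
    "mask_mar",
    "impute_sequential",
    "pool_posteriors",
]

#: variables that may be masked / imputed
MASKABLE: tuple[str, ...] = GH_SCALES + OH_INDICATORS + ("informal_caregiver", "living_alone")

DEFAULT_RATES = {
    "ADL": 0.06,
    "CPS": 0.06,
    "DRS": 0.06,
    "informal_caregiver": 0.06,
    "NT": 0.17,
    "CD": 0.17,
    "DM": 0.17,
    "CHESS": 0.23,
}


class ImputationError(ValueError):
    pass


@dataclass
class MissingnessSpec:
    """Target missingness rates and the MAR mechanism driving them."""

    target_rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    mar_predictors: tuple = ("age_baseline", "gender", "visit_index")
    mar_strength: float = 0.5  # log-odds per SD of the predictor score

    def __post_init__(self) -> None:
        for var, rate in self.target_rates.items():
            if var not in MASKABLE:
                raise ValueError(f"cannot mask always-observed variable {var!r}")
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"rate for {var} must be in [0,1), got {rate}")
            if var in self.mar_predictors:
                raise ValueError(f"{var} cannot predict its own missingness (MAR)")


def _mar_score(df: pd.DataFrame, predictors) -> np.ndarray:
    cols = []
    for name in predictors:
        if name == "gender":
            v = (df["gender"] == "female").to_numpy(float)
        else:
            v = df[name].to_numpy(float)
        sd = v.std()
        cols.append((v - v.mean()) / sd if sd > 0 else np.zeros(len(v)))
    z = np.sum(cols, axis=0) / np.sqrt(len(cols))
    return z


def mask_mar(cohort: Cohort, spec: MissingnessSpec, seed: int) -> Cohort:
    """Set cells to missing at the target rates under a MAR mechanism.

    For each variable the masking probability is expit(c + strength * z) with
    z a standardized score of the always-observed predictors and c solved so
    the expected rate equals the target; deterministic given ``seed``.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    df = cohort.data.copy()
    z = _mar_score(df, spec.mar_predictors)
    for var, rate in spec.target_rates.items():
        if rate == 0.0:
            continue
        if spec.mar_strength == 0.0:
            p = np.full(len(df), rate)
        else:
            c = brentq(
                lambda c0: expit(c0 + spec.mar_strength * z).mean() - rate, -40, 40
            )
            p = expit(c + spec.mar_strength * z)
        hit = rng.uniform(size=len(df)) < p
        col = df[var].to_numpy(dtype="float")
        df[var] = pd.array(np.where(hit, np.nan, col), dtype="Int64")
    return Cohort(df, provenance=cohort.provenance + f" | masked seed={seed}")


# ---------------------------------------------------------------------------
# sequential imputation
# ---------------------------------------------------------------------------

#: predictor vocabulary available to every imputation model
_IMP_PREDICTORS = (
    "age_c",
    "female",
    "int_night_care",
    "int_occupational_therapy",
    "int_other",
    "time",
) + tuple(MASKABLE)


@dataclass
class ImputationModelSequence:
    """Ordered chained-imputation plan.

    ``targets`` default to every incomplete variable ordered from least to
    most missing; each binary target gets a Bayesian logistic model, each
    ordinal target a cumulative-logit model, with all other analysis
    variables (plus visit index and baseline covariates) as predictors.
    """

    targets: tuple | None = None  # imputation order; None = auto
    n_imputations: int = 5
    n_cycles: int = 2
    predictors: dict | None = None  # per-target predictor tuples (default: all others)
    families: dict | None = None  # per-target "binary"/"ordinal" overrides

    def resolved_targets(self, df: pd.DataFrame) -> list:
        if self.targets is not None:
            order = list(self.targets)
            if len(set(order)) != len(order):
                raise ImputationError("each imputation target may appear only once")
        else:
            frac = {v: df[v].isna().mean() for v in MASKABLE if df[v].isna().any()}
            order = sorted(frac, key=lambda v: (frac[v], v))
        return order


def _laplace_model_draw(y, X, family: str, rng):
    """Fit a Bayesian GLM by MAP + Laplace and return (predict_probs, levels).

    ``predict_probs(Xnew)`` uses a single parameter draw from the normal
    posterior approximation; degenerate responses fall back to the observed
    marginal.
    """
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    levels = np.unique(y)
    if len(levels) < 2:
        return (lambda Xn: np.ones((len(Xn), 1))), levels
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "binary":
                model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
                res = model.fit(disp=0, method="lbfgs", maxiter=200)
                theta = rng.multivariate_normal(res.params, res.cov_params())

                def predict(Xn, theta=theta):
                    return_probs = expit(sm.add_constant(Xn, has_constant="add") @ theta)
                    return np.column_stack([1 - return_probs, return_probs])

            else:
                model = OrderedModel(y, X, distr="logit")
                res = model.fit(method="bfgs", disp=0, maxiter=200)
                theta = rng.multivariate_normal(res.params, res.cov_params())

                def predict(Xn, model=model, theta=theta):
                    return np.asarray(model.predict(theta, exog=Xn))

        if not np.all(np.isfinite(predict(X[:2]))):
            raise ValueError("non-finite predictions")
        return predict, levels
    except Exception:
        # separation / singular fits: marginal posterior-predictive fallback
        counts = np.bincount(np.searchsorted(levels, y)) + 0.5
        probs = rng.dirichlet(counts)
        return (lambda Xn, p=probs: np.tile(p, (len(Xn), 1))), levels


def _imp_design(df: pd.DataFrame, target: str, seq: "ImputationModelSequence") -> np.ndarray:
    from .design import build_design

    if seq.predictors and target in seq.predictors:
        preds = tuple(seq.predictors[target])
    else:
        preds = tuple(p for p in _IMP_PREDICTORS if p != target)
    if target in preds:
        raise ImputationError(f"{target} cannot predict itself")
    return build_design(df, preds)


def impute_sequential(
    cohort: Cohort, seq: ImputationModelSequence | None = None, seed: int = 0
) -> list:
    """Produce M completed cohorts by chained Bayesian imputation.

    Observed cells are never altered; every imputed value is a
    posterior-predictive draw from its variable's (chained) model, and each of
    the M datasets uses an independent posterior parameter draw.
    """
    seq = seq or ImputationModelSequence()
    df0 = cohort.data
    order = seq.resolved_targets(df0)
    for var in order:
        if df0[var].isna().all():
            raise ImputationError(f"{var} is 100% missing: no information to impute from")
    other_na = [
        v for v in MASKABLE if v not in order and df0[v].isna().any()
    ]
    if other_na:
        raise ImputationError(f"variables missing but not in the sequence: {other_na}")
    if not order:
        return [cohort.copy() for _ in range(seq.n_imputations)]

    na_mask = {v: df0[v].isna().to_numpy() for v in order}
    completed = []
    ss = np.random.SeedSequence([int(seed) % 2**31, 4242])
    for m, state in enumerate(ss.generate_state(seq.n_imputations)):
        rng = np.random.default_rng(int(state) % 2**31)
        work = df0.copy()
        # initial fill: draws from each variable's observed marginal
        for var in order:
            obs = work[var].dropna().to_numpy(int)
            fill = rng.choice(obs, size=int(na_mask[var].sum()), replace=True)
            col = work[var].to_numpy("float")
            col[na_mask[var]] = fill
            work[var] = pd.array(col, dtype="Int64")
        for _ in range(seq.n_cycles):
            for var in order:
                X = _imp_design(work, var, seq)
                obs = ~na_mask[var]
                y_obs = work.loc[obs, var].to_numpy(int)
                if seq.families and var in seq.families:
                    family = seq.families[var]
                elif var in OH_INDICATORS + BINARY_COVARIATES:
                    family = "binary"
                else:
                    family = "ordinal"
                predict, levels = _laplace_model_draw(y_obs, X[obs], family, rng)
                if na_mask[var].any():
                    probs = predict(X[na_mask[var]])
                    cum = np.cumsum(probs, axis=1)
                    cum /= cum[:, -1:]
                    pick = (rng.uniform(size=len(probs))[:, None] > cum).sum(axis=1)
                    col = work[var].to_numpy("float")
                    col[na_mask[var]] = levels[np.minimum(pick, len(levels) - 1)]
                    work[var] = pd.array(col, dtype="Int64")
        out = Cohort(work, provenance=cohort.provenance + f" | imputation {m + 1}")
        out.validate()
        completed.append(out)
    return completed


def pool_posteriors(fits: list) -> PosteriorDraws:
    """Mixture-of-posteriors pooling across multiply-imputed fits.

    Draws are concatenated (per chain); summaries computed on the pooled set
    therefore satisfy the mixture moment identities (pooled variance =
    average within-imputation variance + between-imputation variance of the
    means).
    """
    return PosteriorDraws.pool(list(fits))


def rubin_summary(fits: list, prob: float = 0.95) -> pd.DataFrame:
    """Rubin's-rules summary of multiply-imputed fits, for comparison.

    Combines per-imputation posterior means/variances as point estimate =
    mean of means, total variance = within + (1 + 1/M) between; intervals use
    the normal approximation.  The package's primary pooling is the
    mixture-of-posteriors concatenation in :func:`pool_posteriors`.
    """
    from scipy.stats import norm

    names = list(fits[0].names)
    M = len(fits)
    means = np.array([[f.mean(n) for n in names] for f in fits])  # (M, P)
    wvar = np.array([[f.pooled(n).var(ddof=1) for n in names] for f in fits])
    qbar = means.mean(axis=0)
    w = wvar.mean(axis=0)
    b = means.var(axis=0, ddof=1) if M > 1 else np.zeros(len(names))
    total = w + (1 + 1 / M) * b
    z = norm.ppf(0.5 + prob / 2)
    return pd.DataFrame(
        {
            "estimate": qbar,
            "se": np.sqrt(total),
            "ci_low": qbar - z * np.sqrt(total),
            "ci_high": qbar + z * np.sqrt(total),
        },
        index=names,
    )
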