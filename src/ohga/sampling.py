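"""Posterior sampling engine.

Model objects expose a vectorized log-posterior over an unconstrained
parameter vector; random intercepts are marginalized out by Gauss-Hermite
quadrature inside the likelihood, so the sampled space is low-dimensional
(~15-25 coordinates) and close to Gaussian.

Sampling uses independence Metropolis-Hastings with a multivariate-t proposal
built from the posterior mode and curvature (Laplace approximation), then
re-estimated once from warmup draws.  The analysis's four chains are run in
lockstep (one batched log-posterior call per iteration) from overdispersed
proposal draws; the kernel is fixed after warmup, so each chain is a genuine
Markov chain and the BGR diagnostic applies directly.

:class:`PosteriorDraws` is the package-wide container for MCMC output:
per-parameter draw matrices laid out as (chains x iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize


class SchemaMismatchError(ValueError):
    """Two draw sets do not share a parameter schema."""


class ConvergenceError(RuntimeError):
    """Chains failed the convergence checks after all allowed extensions."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "MCMC did not converge: "
            + ", ".join(f"{p} (rhat={r:.3f})" for p, r in report.failures())
        )


@dataclass
class PosteriorDraws:
    """Named posterior draws, shape (chains, iterations, parameters)."""

    names: list
    array: np.ndarray
    diagnostics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, float)
        if self.array.ndim != 3 or self.array.shape[2] != len(self.names):
            raise ValueError("draws array must be (chains, iterations, len(names))")

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.array.shape[1]

    def _idx(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaMismatchError(f"no parameter named {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """Draw matrix (chains x iterations) for one parameter."""
        return self.array[:, :, self._idx(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def median(self, name: str) -> float:
        return float(np.median(self.pooled(name)))

    def interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        tail = (1.0 - prob) / 2.0
        lo, hi = np.quantile(self.pooled(name), [tail, 1.0 - tail])
        return float(lo), float(hi)

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        tail = (1.0 - prob) / 2.0
        flat = self.array.reshape(-1, len(self.names))
        qs = np.quantile(flat, [tail, 0.5, 1.0 - tail], axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "median": qs[1],
                "sd": flat.std(axis=0, ddof=1),
                "ci_low": qs[0],
                "ci_high": qs[2],
            },
            index=list(self.names),
        )

    @classmethod
    def pool(cls, fits: list) -> "PosteriorDraws":
        """Mixture-of-posteriors pooling: concatenate draws per chain."""
        if not fits:
            raise ValueError("nothing to pool")
        ref = fits[0]
        for f in fits[1:]:
            if list(f.names) != list(ref.names):
                extra = set(f.names) ^ set(ref.names)
                raise SchemaMismatchError(f"parameter schema mismatch: {sorted(extra)}")
            if f.array.shape[0] != ref.array.shape[0]:
                raise SchemaMismatchError("pooled fits must have the same chain count")
        arr = np.concatenate([f.array for f in fits], axis=1)
        diags = [d for f in fits for d in f.diagnostics]
        return cls(list(ref.names), arr, diags)

    def save(self, path) -> str:
        np.savez_compressed(path, names=np.array(self.names, dtype=object), draws=self.array)
        return str(path)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=True) as z:
            return cls(list(z["names"]), z["draws"])


# ---------------------------------------------------------------------------
# MAP + Laplace approximation (batched finite differences)
# ---------------------------------------------------------------------------

def _chunked_logp(model, pts: np.ndarray, max_batch: int = 64) -> np.ndarray:
    """Evaluate the model log posterior in memory-bounded chunks."""
    pts = np.atleast_2d(pts)
    if len(pts) <= max_batch:
        return model.logp(pts)
    return np.concatenate(
        [model.logp(pts[i : i + max_batch]) for i in range(0, len(pts), max_batch)]
    )


def find_map(model, x0: np.ndarray | None = None, maxiter: int = 200):
    """Posterior mode and a curvature-based scale per coordinate.

    The gradient of the log posterior is computed by central differences, all
    2*ndim perturbation points evaluated in one vectorized call.
    """
    d = model.ndim
    x0 = model.initial_point() if x0 is None else np.asarray(x0, float)

    def neg_logp_and_grad(x):
        h = 1e-5 * (1.0 + np.abs(x))
        pts = np.vstack([x, x + np.diag(h), x - np.diag(h)])
        vals = _chunked_logp(model, pts)
        f = vals[0]
        g = (vals[1 : 1 + d] - vals[1 + d :]) / (2.0 * h)
        if not np.isfinite(f):
            return 1e100, np.zeros(d)
        return -f, -np.where(np.isfinite(g), g, 0.0)

    # the mode seeds an MH proposal: moderate precision suffices
    res = minimize(neg_logp_and_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": 1e-3, "ftol": 1e-8})
    x = res.x if np.isfinite(res.fun) else x0

    h2 = 1e-3 * (1.0 + np.abs(x))
    pts = np.vstack([x, x + np.diag(h2), x - np.diag(h2)])
    vals = _chunked_logp(model, pts)
    curv = -(vals[1 : 1 + d] - 2.0 * vals[0] + vals[1 + d :]) / h2**2
    with np.errstate(invalid="ignore"):
        scale = 1.0 / np.sqrt(np.clip(curv, 1e-2, None))
    scale = np.where(np.isfinite(scale), np.minimum(scale, 3.0), 0.5)
    return x, scale


def laplace_covariance(model, x: np.ndarray) -> np.ndarray:
    """Inverse negative Hessian at ``x`` via batched central differences.

    The Hessian is symmetrized and its spectrum floored so the result is a
    valid (positive definite) covariance even when far tails are flat.
    """
    d = model.ndim
    h = 1e-3 * (1.0 + np.abs(x))
    pts = [x]
    idx = []
    for i in range(d):
        for j in range(i, d):
            if i == j:
                pts += [x + 2 * h[i] * _e(i, d), x - 2 * h[i] * _e(i, d)]
            else:
                hi, hj = h[i] * _e(i, d), h[j] * _e(j, d)
                pts += [x + hi + hj, x + hi - hj, x - hi + hj, x - hi - hj]
            idx.append((i, j))
    vals = _chunked_logp(model, np.asarray(pts))
    f0 = vals[0]
    H = np.zeros((d, d))
    k = 1
    for (i, j) in idx:
        if i == j:
            H[i, i] = (vals[k] - 2 * f0 + vals[k + 1]) / (4 * h[i] ** 2)
            k += 2
        else:
            H[i, j] = H[j, i] = (vals[k] - vals[k + 1] - vals[k + 2] + vals[k + 3]) / (
                4 * h[i] * h[j]
            )
            k += 4
    neg = -H
    neg = np.where(np.isfinite(neg), neg, 0.0)
    w, V = np.linalg.eigh((neg + neg.T) / 2.0)
    w = np.clip(w, max(1e-4, 1e-6 * w.max()), None)
    return (V / w) @ V.T


def _e(i: int, d: int) -> np.ndarray:
    v = np.zeros(d)
    v[i] = 1.0
    return v


# ---------------------------------------------------------------------------
# multivariate-t proposal
# ---------------------------------------------------------------------------

class _TProposal:
    """Multivariate Student-t proposal with fixed location and scale."""

    def __init__(self, mean: np.ndarray, cov: np.ndarray, df: float = 7.0):
        self.mean = np.asarray(mean, float)
        self.df = float(df)
        d = len(self.mean)
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        w = np.clip(w, 1e-12, None)
        self._L = V * np.sqrt(w)
        self._Linv = (V / np.sqrt(w)).T
        self._logdet = 0.5 * np.log(w).sum()
        self.d = d

    def draw(self, rng, n: int) -> np.ndarray:
        z = rng.standard_normal((n, self.d))
        g = rng.chisquare(self.df, size=n) / self.df
        return self.mean + (z @ self._L.T) / np.sqrt(g)[:, None]

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        u = (np.atleast_2d(x) - self.mean) @ self._Linv.T
        m = (u**2).sum(axis=1)
        return -0.5 * (self.df + self.d) * np.log1p(m / self.df) - self._logdet


# ---------------------------------------------------------------------------
# chain runner (the resumable sampler handle)
# ---------------------------------------------------------------------------

class MHRunner:
    """Independence Metropolis-Hastings chains over one model posterior.

    Resumable: :meth:`extend` continues sampling with the post-warmup kernel,
    so the MCSE-based stopping rule can lengthen converged chains until the
    precision target is met.
    """

    def __init__(self, model, config, seed: int):
        self.model = model
        self.config = config
        ss = np.random.SeedSequence([int(seed) % (2**31), 777])
        self.rng = np.random.default_rng(ss)
        self._started = False
        self._draws: list[np.ndarray] = []  # per-extension (C, n, d) blocks
        self.accept_rate = np.nan

    def _step_block(self, n: int) -> np.ndarray:
        """Advance all chains ``n`` iterations; returns (C, n, d) states."""
        C = self.config.n_chains
        out = np.empty((C, n, self.model.ndim))
        x, lp = self._state, self._state_lp
        lq = self.prop.logpdf(x)
        props = self.prop.draw(self.rng, n * C).reshape(n, C, -1)
        us = np.log(self.rng.uniform(size=(n, C)))
        n_acc = 0
        for t in range(n):
            y = props[t]
            lpy = self.model.logp(y)
            lqy = self.prop.logpdf(y)
            acc = us[t] < (lpy - lp) + (lq - lqy)
            x = np.where(acc[:, None], y, x)
            lp = np.where(acc, lpy, lp)
            lq = np.where(acc, lqy, lq)
            out[:, t] = x
            n_acc += int(acc.sum())
        self._state, self._state_lp = x, lp
        self._block_accept = n_acc / (n * C)
        return out

    def ensure_started(self) -> None:
        if self._started:
            return
        cfg = self.config
        center, _ = find_map(self.model)
        cov = laplace_covariance(self.model, center)
        # moderately heavy-tailed, slightly inflated proposal: robust to the
        # skew of variance-component posteriors at small n
        self.prop = _TProposal(center, 1.2 * cov, df=7.0)
        # overdispersed start: t-proposal draws, retried until finite
        C = cfg.n_chains
        x = self.prop.draw(self.rng, C)
        lp = self.model.logp(x)
        for _ in range(50):
            bad = ~np.isfinite(lp)
            if not bad.any():
                break
            x[bad] = self.prop.draw(self.rng, int(bad.sum()))
            lp = self.model.logp(x)
        x[~np.isfinite(lp)] = center
        self._state, self._state_lp = x, self.model.logp(x)

        warm = self._step_block(cfg.n_warmup)
        flat = warm[:, cfg.n_warmup // 2 :, :].reshape(-1, self.model.ndim)
        if 0.02 < self._block_accept < 0.15 and len(flat) >= 4 * self.model.ndim:
            # Laplace shape badly off: re-estimate the kernel once from warmup
            # draws, then keep it fixed
            cov = np.cov(flat.T) if self.model.ndim > 1 else np.atleast_2d(np.var(flat))
            self.prop = _TProposal(
                flat.mean(axis=0), 1.2 * cov + 1e-10 * np.eye(self.model.ndim), df=7.0
            )
        self._started = True
        self.accepted = 0
        self.total = 0
        self.extend(cfg.n_draws)

    def extend(self, n_iterations: int) -> None:
        self.ensure_started()
        self._draws.append(self._step_block(n_iterations))
        self.total += n_iterations * self.config.n_chains
        self.accepted += int(round(self._block_accept * n_iterations * self.config.n_chains))
        self.accept_rate = self.accepted / self.total

    # -- draw views ----------------------------------------------------------
    def _raw(self) -> np.ndarray:
        return np.concatenate(self._draws, axis=1)  # (C, I, d)

    def posterior_draws(self) -> PosteriorDraws:
        """Constrained draws, (chains, iterations, reported parameters)."""
        raw = self._raw()
        c, i, d = raw.shape
        con = self.model.constrain(raw.reshape(c * i, d))
        return PosteriorDraws(list(self.model.param_names), con.reshape(c, i, -1))

    def diagnostic_chains(self) -> np.ndarray:
        """Alias of the chain view used by the convergence checks."""
        return self.posterior_draws().array


def sample_posterior(model, config, seed: int):
    """MAP-initialize, sample and convergence-check one model posterior.

    Returns (PosteriorDraws, DiagnosticsReport); raises
    :class:`ConvergenceError` when ``config.strict`` and the checks fail after
    ``config.max_extensions`` extensions.
    """
    from .diagnostics import run_until_converged

    runner = MHRunner(model, config, seed)
    draws, report = run_until_converged(runner, config)
    report.meta["accept_rate"] = runner.accept_rate
    draws.diagnostics = [report]
    if config.strict and not report.passed:
        raise ConvergenceError(report)
    return draws, report
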