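"""MCMC convergence machinery: split-R-hat (BGR), ESS, MCSE, stopping rule.

The analysis practice being reproduced: four chains per model, convergence
checked with the Brooks-Gelman-Rubin potential scale reduction factor, then
sampling continued until every parameter's Monte Carlo standard error is
below 5% of its posterior SD.  R-hat/ESS estimation is delegated to arviz
(split method, i.e. the classical non-rank-normalized diagnostic; a flag
switches to the rank-normalized variant).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MCMCConfig:
    """Sampler settings shared by every model fit."""

    n_chains: int = 4
    n_warmup: int = 300
    n_draws: int = 500
    max_extensions: int = 2
    rhat_threshold: float = 1.1
    mcse_ratio_threshold: float = 0.05
    strict: bool = True  # raise on non-convergence inside model fits

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the BGR diagnostic")
        if self.rhat_threshold <= 0 or self.mcse_ratio_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _as_chain_matrix(draws) -> np.ndarray:
    arr = np.asarray(draws, float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("draws must be 1-D or (chains, iterations)")
    return arr


def gelman_rubin(draws, rank_normalized: bool = False) -> float:
    """Split-chain potential scale reduction factor (BGR diagnostic).

    ``draws`` is (chains, iterations) with >= 2 chains and >= 4 iterations.
    Draws that are constant across all chains give 1.0 by convention.
    """
    import arviz as az

    arr = _as_chain_matrix(draws)
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("gelman_rubin needs >= 2 chains of >= 4 iterations")
    if np.ptp(arr) == 0.0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        method = "rank" if rank_normalized else "split"
        return float(az.rhat(arr, method=method))


def ess(draws) -> float:
    """Autocorrelation-based effective sample size (sum over chains)."""
    import arviz as az

    arr = _as_chain_matrix(draws)
    if np.ptp(arr) == 0.0:
        return float(arr.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr, method="mean"))


def mcse(draws) -> float:
    """Monte Carlo standard error of the posterior mean: SD / sqrt(ESS)."""
    arr = _as_chain_matrix(draws)
    if arr.size < 100:
        raise ValueError(f"mcse needs >= 100 draws, got {arr.size}")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return 0.0
    return sd / np.sqrt(ess(arr))


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence table with pass/fail flags."""

    table: pd.DataFrame
    rhat_threshold: float
    mcse_ratio_threshold: float
    n_extensions: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.table["pass"].all())

    def failures(self) -> list:
        bad = self.table[~self.table["pass"]]
        return list(zip(bad.index, bad["rhat"]))

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "n_extensions": self.n_extensions,
            "rhat_threshold": self.rhat_threshold,
            "mcse_ratio_threshold": self.mcse_ratio_threshold,
            "parameters": self.table.reset_index().rename(columns={"index": "param"}).to_dict(
                orient="records"
            ),
        }

    def to_json(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return str(path)


def diagnose(chains: np.ndarray, names, config: MCMCConfig) -> DiagnosticsReport:
    """Diagnostics on a (chains, iterations, params) array of draws."""
    rows = []
    for j, name in enumerate(names):
        mat = chains[:, :, j]
        sd = float(mat.std(ddof=1))
        if sd == 0.0:
            rows.append((name, 1.0, float(mat.size), 0.0, 0.0, 0.0))
            continue
        r = gelman_rubin(mat)
        e = ess(mat)
        m = sd / np.sqrt(max(e, 1.0))
        rows.append((name, r, e, sd, m, m / sd))
    tab = pd.DataFrame(
        rows, columns=["param", "rhat", "ess", "sd", "mcse", "mcse_ratio"]
    ).set_index("param")
    tab["pass"] = (tab["rhat"] < config.rhat_threshold) & (
        tab["mcse_ratio"] < config.mcse_ratio_threshold
    )
    return DiagnosticsReport(tab, config.rhat_threshold, config.mcse_ratio_threshold)


def run_until_converged(runner, config: MCMCConfig):
    """Extend sampling until R-hat and the MCSE/SD ratio pass, or give up.

    ``runner`` is a resumable sampler handle (:class:`ohga.sampling.MHRunner`
    or anything exposing ``ensure_started``, ``extend`` and
    ``posterior_draws``).  Failure after ``max_extensions`` is reported via
    the returned :class:`DiagnosticsReport`, never raised, so pipelines can
    log and halt cleanly.
    """
    runner.ensure_started()
    ext = 0
    while True:
        draws = runner.posterior_draws()
        report = diagnose(draws.array, draws.names, config)
        report.n_extensions = ext
        if report.passed or ext >= config.max_extensions:
            return draws, report
        runner.extend(config.n_draws)
        ext += 1


def trace_plot(draws, names=None, path=None):
    """Optional visual check; written as an image, never used programmatically."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(names or draws.names)
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 1.8 * len(names)), squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        for c in range(draws.n_chains):
            ax.plot(draws.get(name)[c], lw=0.4)
        ax.set_ylabel(name)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return str(path)
    return fig
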