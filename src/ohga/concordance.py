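"""Observed-vs-predicted contingency tables and concordance percentages.

The model-fit surface of the first analysis: for each GH scale the posterior-
median predicted category of every record is cross-tabulated against the
observed category, and the share of records predicted exactly right
(``pct_exact``) or within one category (``pct_within_one``) summarizes fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .propodds import POModelSpec, posterior_predict_categories
from .sampling import PosteriorDraws

__all__ = [
    "ContingencyTable",
    "ConcordanceSummary",
    "build_contingency",
    "concordance",
    "evaluate_fit",
]


@dataclass
class ContingencyTable:
    """K x K counts; rows = observed category, columns = predicted."""

    counts: np.ndarray
    scale: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        k = self.counts.shape[0]
        return pd.DataFrame(
            self.counts,
            index=pd.Index(range(k), name="observed"),
            columns=pd.Index(range(k), name="predicted"),
        )

    def to_csv(self, path) -> str:
        """Counts block followed by the row-percentage block."""
        frame = self.to_frame()
        pct = concordance(self).row_percentages
        pct_frame = pd.DataFrame(np.round(pct, 1), index=frame.index, columns=frame.columns)
        with open(path, "w") as fh:
            fh.write(f"# scale: {self.scale}\n# counts\n")
            frame.to_csv(fh)
            fh.write("# row percentages\n")
            pct_frame.to_csv(fh)
        return str(path)


@dataclass
class ConcordanceSummary:
    """Exact / within-one-category concordance percentages."""

    pct_exact: float
    pct_within_one: float
    row_percentages: np.ndarray
    scale: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_exact <= self.pct_within_one <= 100.0:
            raise ValueError("need 0 <= pct_exact <= pct_within_one <= 100")

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "pct_exact": self.pct_exact,
            "pct_within_one": self.pct_within_one,
        }


def build_contingency(observed, predicted, K: int, scale: str = "") -> ContingencyTable:
    """Cross-tabulate observed x predicted categories (codes 0..K-1)."""
    obs = np.asarray(observed, int)
    pred = np.asarray(predicted, int)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} observed vs {pred.shape} predicted")
    for name, v in (("observed", obs), ("predicted", pred)):
        bad = np.flatnonzero((v < 0) | (v > K - 1))
        if len(bad):
            raise ValueError(f"{name}[{bad[0]}]={v[bad[0]]} outside 0..{K - 1}")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (obs, pred), 1)
    return ContingencyTable(counts, scale)


def pct_within(table: ContingencyTable, band: int) -> float:
    """Percentage of records with |observed - predicted| <= band."""
    if table.total == 0:
        raise ValueError("empty contingency table")
    k = table.counts.shape[0]
    o, p = np.indices((k, k))
    return 100.0 * table.counts[np.abs(o - p) <= band].sum() / table.total


def concordance(table: ContingencyTable) -> ConcordanceSummary:
    """Exact and within-one concordance plus row-normalized percentages."""
    if table.total == 0:
        raise ValueError("empty contingency table")
    rowsum = table.counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore"):
        rowpct = np.where(rowsum > 0, 100.0 * table.counts / rowsum, 0.0)
    return ConcordanceSummary(
        pct_exact=pct_within(table, 0),
        pct_within_one=pct_within(table, 1),
        row_percentages=rowpct,
        scale=table.scale,
    )


def evaluate_fit(
    draws: PosteriorDraws,
    cohort: Cohort,
    spec: POModelSpec,
    seed: int,
    n_draws: int = 200,
) -> tuple[ContingencyTable, ConcordanceSummary]:
    """In-sample observed-vs-predicted evaluation of one proportional-odds fit."""
    pred = posterior_predict_categories(draws, cohort, spec, seed=seed, n_draws=n_draws)
    obs = cohort.data[spec.response].to_numpy(int)
    table = build_contingency(obs, pred, spec.n_categories, scale=spec.response)
    return table, concordance(table)
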