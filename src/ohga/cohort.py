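"""Long-format cohort container, CSV I/O and inclusion/exclusion filters.

A cohort is one row per subject-visit carrying the three binary OH items, the
four ordinal GH scales, two binary time-varying covariates and the baseline
covariates (age at baseline, gender, intervention type) repeated on every row.
Missing cells are pandas NA (empty cells in CSV).

The inclusion filters reproduce the registry-extraction rules: subjects must
be older than 65 at baseline, subjects without a known birth date or with a
missing assessment date are dropped, and repeated assessments must fall
within five to seven months of the previous one.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .scales import SCALES, GENDERS, INTERVENTIONS, GH_SCALES, OH_INDICATORS, BINARY_COVARIATES

#: average month length in days used for visit-gap arithmetic (timezone-free)
DAYS_PER_MONTH = 30.4375

COLUMNS: tuple[str, ...] = (
    "subject_id",
    "visit_index",
    "assessment_date",
    "age_baseline",
    "gender",
    "intervention",
    "living_alone",
    "informal_caregiver",
    "NT",
    "CD",
    "DM",
    "ADL",
    "CPS",
    "DRS",
    "CHESS",
)

#: columns holding small-integer codes with a known range
_CODED = {name: SCALES[name].n_categories for name in GH_SCALES + OH_INDICATORS}
_CODED.update({name: 2 for name in BINARY_COVARIATES})


class SchemaError(ValueError):
    """CSV header does not match the documented cohort schema."""


class CohortValidationError(ValueError):
    """A cell violates the schema (out-of-range code, malformed value...)."""


@dataclass
class Cohort:
    """Validated long-format collection of assessment records.

    ``data`` has the columns in :data:`COLUMNS`; coded columns are nullable
    Int64, ``assessment_date`` is datetime64, ``age_baseline`` float (NaN if
    the birth date is unknown).
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort frame lacks columns: {missing}")
        self.data = self.data.loc[:, list(COLUMNS)].reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def baselines(self) -> pd.DataFrame:
        """One row per subject with the baseline covariates."""
        cols = ["subject_id", "age_baseline", "gender", "intervention"]
        return self.data[cols].drop_duplicates("subject_id").reset_index(drop=True)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.provenance)

    # -- validation --------------------------------------------------------
    def validate(self, filtered: bool = False) -> None:
        """Raise :class:`CohortValidationError` on any invariant violation.

        With ``filtered=True`` also checks the post-filter invariants:
        consecutive 1-based visit indices and inter-visit gaps in [5,7]
        months.
        """
        df = self.data
        for name, k in _CODED.items():
            vals = df[name].dropna()
            bad = vals[(vals < 0) | (vals > k - 1)]
            if len(bad):
                row = int(bad.index[0])
                raise CohortValidationError(
                    f"{name}={bad.iloc[0]} out of range 0..{k - 1} at row {row}"
                )
        bad_gender = df["gender"].dropna()[~df["gender"].dropna().isin(GENDERS)]
        if len(bad_gender):
            raise CohortValidationError(f"unknown gender {bad_gender.iloc[0]!r}")
        bad_int = df["intervention"].dropna()[~df["intervention"].dropna().isin(INTERVENTIONS)]
        if len(bad_int):
            raise CohortValidationError(f"unknown intervention {bad_int.iloc[0]!r}")
        base = df.groupby("subject_id")[["age_baseline", "gender", "intervention"]].nunique(dropna=False)
        incons = base[(base > 1).any(axis=1)]
        if len(incons):
            raise CohortValidationError(
                f"subject {incons.index[0]!r} has inconsistent baseline covariates"
            )
        if filtered:
            for sid, grp in df.groupby("subject_id", sort=False):
                vi = grp["visit_index"].to_numpy()
                if not np.array_equal(np.sort(vi), np.arange(1, len(vi) + 1)):
                    raise CohortValidationError(
                        f"subject {sid!r}: visit_index not consecutive from 1"
                    )
                dates = grp.sort_values("visit_index")["assessment_date"]
                gaps = dates.diff().dropna().dt.days.to_numpy() / DAYS_PER_MONTH
                if len(gaps) and ((gaps < 5.0) | (gaps > 7.0)).any():
                    raise CohortValidationError(
                        f"subject {sid!r}: inter-visit gap outside [5,7] months"
                    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_int(raw: str, name: str, row: int, k: int) -> object:
    if raw == "":
        return pd.NA
    try:
        v = int(raw)
    except ValueError:
        raise CohortValidationError(f"row {row}: {name}={raw!r} is not an integer") from None
    if not 0 <= v <= k - 1:
        raise CohortValidationError(f"row {row}: {name}={v} out of range 0..{k - 1}")
    return v


def read_cohort(path, provenance: str | None = None) -> Cohort:
    """Read a long-format cohort CSV, validating every cell.

    Unknown or missing header columns raise :class:`SchemaError`; malformed
    or out-of-range category values raise :class:`CohortValidationError`
    naming the row.  Empty cells become missing values.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")

    out: dict[str, list] = {c: [] for c in COLUMNS}
    for row, rec in enumerate(raw.itertuples(index=False)):
        rec = rec._asdict()
        sid = rec["subject_id"]
        if sid == "":
            raise CohortValidationError(f"row {row}: empty subject_id")
        out["subject_id"].append(sid)
        try:
            vi = int(rec["visit_index"])
        except ValueError:
            raise CohortValidationError(
                f"row {row}: visit_index={rec['visit_index']!r} is not an integer"
            ) from None
        out["visit_index"].append(vi)
        d = rec["assessment_date"]
        if d == "":
            out["assessment_date"].append(pd.NaT)
        else:
            try:
                out["assessment_date"].append(pd.Timestamp(_dt.date.fromisoformat(d)))
            except ValueError:
                raise CohortValidationError(
                    f"row {row}: assessment_date={d!r} is not an ISO date"
                ) from None
        a = rec["age_baseline"]
        out["age_baseline"].append(float(a) if a != "" else np.nan)
        for name in ("gender", "intervention"):
            v = rec[name]
            allowed = GENDERS if name == "gender" else INTERVENTIONS
            if v != "" and v not in allowed:
                raise CohortValidationError(f"row {row}: unknown {name} {v!r}")
            out[name].append(v if v != "" else pd.NA)
        for name, k in _CODED.items():
            out[name].append(_parse_int(rec[name], name, row, k))

    df = pd.DataFrame(out)
    for name in _CODED:
        df[name] = df[name].astype("Int64")
    df["assessment_date"] = pd.to_datetime(df["assessment_date"])
    c = Cohort(df, provenance or str(path))
    c.validate()
    return c


def write_cohort(cohort: Cohort, path) -> str:
    """Write a cohort CSV (UTF-8, empty cells for missing); returns ``path``.

    Rows are ordered by (subject_id, visit_index) so output is byte-stable.
    ``read_cohort(write_cohort(c)) == c`` up to row order.
    """
    df = cohort.data.sort_values(["subject_id", "visit_index"], kind="stable")
    out = pd.DataFrame(index=df.index)
    out["subject_id"] = df["subject_id"]
    out["visit_index"] = df["visit_index"].astype(int).astype(str)
    out["assessment_date"] = (
        pd.to_datetime(df["assessment_date"]).dt.strftime("%Y-%m-%d").fillna("")
    )
    out["age_baseline"] = df["age_baseline"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out["gender"] = df["gender"].fillna("")
    out["intervention"] = df["intervention"].fillna("")
    for name in _CODED:
        out[name] = df[name].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out = out.loc[:, list(COLUMNS)]
    out.to_csv(path, index=False, lineterminator="\n")
    return str(path)


# ---------------------------------------------------------------------------
# Inclusion / exclusion filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Exclusion counts produced by :func:`apply_inclusion_filters`."""

    n_subjects_in: int = 0
    n_records_in: int = 0
    n_subjects_out: int = 0
    n_records_out: int = 0
    subjects_under_age: int = 0
    subjects_missing_age: int = 0
    subjects_missing_date: int = 0
    records_gap_dropped: int = 0
    reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def apply_inclusion_filters(
    cohort: Cohort,
    min_age: float = 65.0,
    gap_window: tuple[float, float] = (5.0, 7.0),
    strict_age: bool = True,
    drop_successors: bool = True,
) -> tuple[Cohort, FilterReport]:
    """Apply the registry inclusion rules; total (never raises on content).

    * subjects with unknown age (birth date) are dropped entirely;
    * subjects with any missing assessment date are dropped entirely;
    * subjects aged <= ``min_age`` at baseline are dropped (``strict_age=False``
      keeps age == min_age);
    * a visit whose gap from the previous retained visit falls outside
      ``gap_window`` (months, inclusive) is dropped, together with all later
      visits when ``drop_successors`` (the chain of 6-monthly assessments is
      broken), otherwise only the violating visit.

    Visit indices are renumbered consecutively from 1.
    """
    df = cohort.data
    report = FilterReport(n_subjects_in=cohort.n_subjects, n_records_in=cohort.n_records)
    lo, hi = gap_window
    kept_parts: list[pd.DataFrame] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values(["visit_index", "assessment_date"], kind="stable")
        if grp["assessment_date"].isna().any():
            report.subjects_missing_date += 1
            continue
        age = grp["age_baseline"].iloc[0]
        if pd.isna(age):
            report.subjects_missing_age += 1
            continue
        ok_age = age > min_age if strict_age else age >= min_age
        if not ok_age:
            report.subjects_under_age += 1
            continue
        dates = grp["assessment_date"].to_numpy()
        keep = [0]
        for j in range(1, len(grp)):
            gap = (dates[j] - dates[keep[-1]]) / np.timedelta64(1, "D") / DAYS_PER_MONTH
            if lo <= gap <= hi:
                keep.append(j)
            else:
                report.records_gap_dropped += 1
                if drop_successors:
                    report.records_gap_dropped += len(grp) - j - 1
                    break
        sub = grp.iloc[keep].copy()
        sub["visit_index"] = np.arange(1, len(sub) + 1)
        kept_parts.append(sub)

    if kept_parts:
        out = pd.concat(kept_parts, ignore_index=True)
    else:
        out = df.iloc[0:0].copy()
    filtered = Cohort(out, provenance=cohort.provenance + " | filtered")
    report.n_subjects_out = filtered.n_subjects
    report.n_records_out = filtered.n_records
    report.reasons = {
        "under_age": report.subjects_under_age,
        "missing_age": report.subjects_missing_age,
        "missing_date": report.subjects_missing_date,
        "gap_violation": report.records_gap_dropped,
    }
    return filtered, report
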