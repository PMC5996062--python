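"""Shared fixed-effects design-matrix construction.

All models use one covariate vocabulary so that generator truths, fitted
coefficients and imputation predictors line up by name:

* ``NT``, ``CD``, ``DM`` — binary OH items (0/1);
* ``age_c`` — baseline age centered at 80 and scaled by 10 years;
* ``female`` — gender indicator (male = reference);
* ``int_night_care``, ``int_occupational_therapy``, ``int_other`` —
  intervention dummies (case management = reference);
* ``time`` — visit_index - 1, in half-year units;
* products written ``a:b`` (intervention x time interactions);
* ``living_alone``, ``informal_caregiver`` — binary time-varying covariates;
* the GH scale names — integer scores (used as imputation predictors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_CENTER = 80.0
AGE_SCALE = 10.0

#: covariates of the first-analysis proportional-odds model, in order
PO_COVARIATES: tuple[str, ...] = (
    "NT",
    "CD",
    "DM",
    "age_c",
    "female",
    "int_night_care",
    "int_occupational_therapy",
    "int_other",
    "time",
    "int_night_care:time",
    "int_occupational_therapy:time",
    "int_other:time",
    "living_alone",
    "informal_caregiver",
)

#: default adjustment set of the second-analysis cross-lagged model
VAR_COVARIATES: tuple[str, ...] = ("age_c", "female", "living_alone", "informal_caregiver")


def _column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "age_c":
        return (df["age_baseline"].to_numpy(float) - AGE_CENTER) / AGE_SCALE
    if name == "female":
        return (df["gender"] == "female").to_numpy(float)
    if name == "time":
        return df["visit_index"].to_numpy(float) - 1.0
    if name.startswith("int_"):
        return (df["intervention"] == name[4:]).to_numpy(float)
    if name in df.columns:
        col = df[name]
        if col.isna().any():
            raise ValueError(
                f"covariate {name!r} has missing values; impute before model fitting"
            )
        return col.to_numpy(float)
    raise KeyError(f"unknown covariate {name!r}")


def build_design(df: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Return the (n_rows, n_covariates) design matrix for ``covariates``."""
    cols = []
    for name in covariates:
        if ":" in name:
            a, b = name.split(":", 1)
            cols.append(_column(df, a) * _column(df, b))
        else:
            cols.append(_column(df, name))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))
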