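"""Indicator definitions for the oral-health / general-health assessment battery.

The general-health (GH) side consists of four ordinal interRAI scales —
Activities of Daily Living (ADL, 0-6), Cognitive Performance Scale (CPS, 0-6),
Depression Rating Scale (DRS, 0-14) and the CHESS health-instability scale
(0-5).  The oral-health (OH) side consists of three binary items: non-intact
teeth (NT), chewing difficulty (CD) and dry mouth (DM).  For every indicator a
higher value means a worse or less stable condition.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScaleSpec:
    """Category structure of one indicator.

    Codes are the integers ``0 .. n_categories - 1``; ``higher_is_worse`` is
    True for every indicator in this battery.
    """

    name: str
    n_categories: int
    higher_is_worse: bool = True

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"{self.name}: n_categories must be >= 2")

    @property
    def max_code(self) -> int:
        return self.n_categories - 1


GH_SCALES: tuple[str, ...] = ("ADL", "CPS", "DRS", "CHESS")
OH_INDICATORS: tuple[str, ...] = ("NT", "CD", "DM")

SCALES: dict[str, ScaleSpec] = {
    "ADL": ScaleSpec("ADL", 7),
    "CPS": ScaleSpec("CPS", 7),
    "DRS": ScaleSpec("DRS", 15),
    "CHESS": ScaleSpec("CHESS", 6),
    "NT": ScaleSpec("NT", 2),
    "CD": ScaleSpec("CD", 2),
    "DM": ScaleSpec("DM", 2),
}

#: binary time-varying covariates carried on each assessment row
BINARY_COVARIATES: tuple[str, ...] = ("living_alone", "informal_caregiver")

GENDERS: tuple[str, ...] = ("female", "male")
INTERVENTIONS: tuple[str, ...] = (
    "case_management",
    "night_care",
    "occupational_therapy",
    "other",
)
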