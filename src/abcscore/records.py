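"""Utstein-style per-patient records and guideline-period assignment.

The record layout follows the Utstein reporting template for out-of-hospital
cardiac arrest (OHCA) registries: prehospital circumstances (witnessed status,
no-flow time, first monitored rhythm, bystander public-access defibrillation),
demographics, and the 1-month cerebral performance category (CPC) outcome.
Fields that a registry export may leave blank are Optional; a missing value is
always represented as None / :data:`Cpc.UNKNOWN`, never as a silent default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Optional


class Cause(str, enum.Enum):
    """Presumed cause of arrest. External causes are exclusion criteria."""

    INTERNAL = "internal"
    EXTERNAL_TRAUMA = "external_trauma"
    EXTERNAL_HYPOTHERMIA = "external_hypothermia"
    EXTERNAL_DROWNING = "external_drowning"
    EXTERNAL_POISONING = "external_poisoning"
    EXTERNAL_OTHER = "external_other"

    @property
    def is_external(self) -> bool:
        return self is not Cause.INTERNAL


class FirstRhythm(str, enum.Enum):
    """First monitored rhythm on EMS arrival."""

    VT = "VT"
    VF = "VF"
    PEA = "PEA"
    ASYSTOLE = "asystole"
    SPONTANEOUS_CIRCULATION = "spontaneous_circulation"

    @property
    def is_shockable(self) -> bool:
        return self in (FirstRhythm.VT, FirstRhythm.VF)


class Region(str, enum.Enum):
    """Kanto (the score's derivation region, excluded) vs the rest of Japan."""

    KANTO = "kanto"
    OTHER = "other"


class Cpc(enum.Enum):
    """Cerebral performance category at 1 month; 1–2 is favourable, 5 is death."""

    CPC1 = 1
    CPC2 = 2
    CPC3 = 3
    CPC4 = 4
    CPC5 = 5
    UNKNOWN = "unknown"

    @property
    def is_known(self) -> bool:
        return self is not Cpc.UNKNOWN

    @property
    def favourable(self) -> bool:
        """CPC 1–2 = favourable neurological outcome."""
        if not self.is_known:
            raise ValueError("outcome is unknown")
        return self.value in (1, 2)


class GuidelineLabel(str, enum.Enum):
    G2005 = "G2005"
    G2010 = "G2010"
    G2015 = "G2015"
    TRANSITION_EXCLUDED = "transition_excluded"


#: Calendar-year spans of the three analysed guideline eras.
GUIDELINE_YEARS: dict[GuidelineLabel, tuple[int, int]] = {
    GuidelineLabel.G2005: (2007, 2009),
    GuidelineLabel.G2010: (2012, 2014),
    GuidelineLabel.G2015: (2017, 2019),
}

#: Year range accepted when loading a real registry export.
REGISTRY_YEAR_RANGE = (2005, 2021)


@dataclass(frozen=True)
class GuidelineGroup:
    """A guideline era with its calendar-year span."""

    label: GuidelineLabel
    year_range: tuple[int, int]


def assign_guideline_group(year: int) -> GuidelineGroup:
    """Map an arrest year to its resuscitation-guideline group.

    Arrests during 2007–2009, 2012–2014 and 2017–2019 fall in the 2005, 2010
    and 2015 guideline groups.  Revision years and the year after each
    revision (and anything outside the analysed window) are transition
    periods, excluded from analysis.
    """
    for label, (lo, hi) in GUIDELINE_YEARS.items():
        if lo <= year <= hi:
            return GuidelineGroup(label, (lo, hi))
    return GuidelineGroup(GuidelineLabel.TRANSITION_EXCLUDED, (year, year))


@dataclass
class UtsteinRecord:
    """One OHCA case as reported Utstein-style.

    ``no_flow_time`` (minutes from witnessed collapse to first chest
    compression) is meaningful only for witnessed arrests; it may be any
    non-negative real.  ``pad_performed`` is bystander public-access
    defibrillation, which by itself satisfies the cardiogram criterion.
    """

    record_id: str
    age: Optional[int] = None
    cause: Optional[Cause] = None
    witnessed: Optional[bool] = None
    no_flow_time: Optional[float] = None
    first_rhythm: Optional[FirstRhythm] = None
    pad_performed: bool = False
    prehospital_rosc: bool = False
    resuscitation_attempted: bool = True
    region: Region = Region.OTHER
    year: int = 0
    cpc: Cpc = Cpc.UNKNOWN

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.no_flow_time is not None and self.no_flow_time < 0:
            raise ValueError(f"no_flow_time must be >= 0, got {self.no_flow_time}")

    @property
    def guideline_group(self) -> GuidelineGroup:
        return assign_guideline_group(self.year)

    def score_computable(self) -> bool:
        """Whether every ABC component is resolvable for this record.

        Requires age and witnessed status; no-flow time whenever the arrest
        was witnessed; and a first rhythm unless public-access defibrillation
        was performed (PAD alone decides the cardiogram component).
        """
        if self.age is None or self.witnessed is None:
            return False
        if self.witnessed and self.no_flow_time is None:
            return False
        if self.first_rhythm is None and not self.pad_performed:
            return False
        return True


FIELD_NAMES: tuple[str, ...] = tuple(f.name for f in fields(UtsteinRecord))
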