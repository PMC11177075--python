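"""The ABC (Age, Bystander, Cardiogram) scoring rule.

One point each for:

* **A** — age 70 years or younger at arrest;
* **B** — bystander factor: witnessed arrest with a no-flow time (collapse to
  first chest compression) of 5 minutes or less; an unwitnessed arrest scores 0;
* **C** — cardiogram: ventricular tachycardia or fibrillation as the first
  monitored rhythm, *or* public-access defibrillation performed by a bystander.

Both thresholds are inclusive; no-flow times are compared as non-negative
reals without flooring.  The total ranges 0–3 and rises with the probability
of a favourable (CPC 1–2) neurological outcome at one month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .records import UtsteinRecord

AGE_CUTOFF = 70  # years, inclusive
NO_FLOW_CUTOFF = 5.0  # minutes, inclusive


class ScoringError(ValueError):
    """A component's inputs are unresolvable (should not occur post-filter)."""


@dataclass(frozen=True)
class ScoreResult:
    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c)):
            if v not in (0, 1):
                raise ValueError(f"component {name} must be 0 or 1, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c


def compute_abc_score(record: UtsteinRecord) -> ScoreResult:
    """Score one record; pure and deterministic.

    Raises :class:`ScoringError` naming the first unresolvable component.
    """
    if record.age is None:
        raise ScoringError(f"record {record.record_id}: age missing (component A)")
    a = 1 if record.age <= AGE_CUTOFF else 0

    if record.witnessed is None:
        raise ScoringError(
            f"record {record.record_id}: witnessed status missing (component B)"
        )
    if record.witnessed:
        if record.no_flow_time is None:
            raise ScoringError(
                f"record {record.record_id}: no-flow time missing for a "
                "witnessed arrest (component B)"
            )
        b = 1 if record.no_flow_time <= NO_FLOW_CUTOFF else 0
    else:
        b = 0

    if record.pad_performed:
        c = 1
    elif record.first_rhythm is None:
        raise ScoringError(
            f"record {record.record_id}: first rhythm missing without "
            "public-access defibrillation (component C)"
        )
    else:
        c = 1 if record.first_rhythm.is_shockable else 0

    return ScoreResult(a=a, b=b, c=c)


def score_cohort(records: Iterable[UtsteinRecord]) -> list[tuple[UtsteinRecord, ScoreResult]]:
    """Score every record of a filtered cohort."""
    return [(rec, compute_abc_score(rec)) for rec in records]
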