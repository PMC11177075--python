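"""Cohort-selection funnel for the score-validation analysis.

Adults with an EMS-attempted resuscitation for an internal-cause arrest are
retained when the ABC score and the 1-month CPC outcome are resolvable, no
prehospital ROSC occurred, the case is outside the score's derivation region
(Kanto), and the arrest year falls in one of the three analysed guideline
eras.  Filters run in a fixed order and each excluded record is tallied at
the first filter it fails, which makes the exclusion log deterministic and
permutation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .records import GuidelineLabel, Region, UtsteinRecord

#: Funnel steps, in application order.
FILTER_STEPS: tuple[str, ...] = (
    "not_attempted_or_under_18",
    "external_cause",
    "score_not_computable",
    "outcome_unknown",
    "prehospital_rosc",
    "kanto_region",
    "transition_year",
)

ADULT_AGE = 18  # inclusive


@dataclass
class ExclusionLog:
    """Ordered tally of records removed at each funnel step."""

    n_input: int = 0
    n_retained: int = 0
    tallies: dict[str, int] = field(
        default_factory=lambda: {step: 0 for step in FILTER_STEPS}
    )

    def check(self) -> None:
        total = sum(self.tallies.values())
        if self.n_input - total != self.n_retained:
            raise AssertionError(
                f"filter accounting broken: {self.n_input} - {total} != {self.n_retained}"
            )

    def as_dict(self) -> dict[str, int]:
        return {"n_input": self.n_input, **self.tallies, "n_retained": self.n_retained}


def _fails_attempt_or_age(rec: UtsteinRecord) -> bool:
    return (
        not rec.resuscitation_attempted or rec.age is None or rec.age < ADULT_AGE
    )


def _fails_cause(rec: UtsteinRecord) -> bool:
    return rec.cause is None or rec.cause.is_external


def _fails_score(rec: UtsteinRecord) -> bool:
    return not rec.score_computable()


def _fails_outcome(rec: UtsteinRecord) -> bool:
    return not rec.cpc.is_known


def _fails_rosc(rec: UtsteinRecord) -> bool:
    return rec.prehospital_rosc


def _fails_region(rec: UtsteinRecord) -> bool:
    return rec.region is Region.KANTO


def _fails_transition(rec: UtsteinRecord) -> bool:
    return rec.guideline_group.label is GuidelineLabel.TRANSITION_EXCLUDED


_PREDICATES: dict[str, Callable[[UtsteinRecord], bool]] = {
    "not_attempted_or_under_18": _fails_attempt_or_age,
    "external_cause": _fails_cause,
    "score_not_computable": _fails_score,
    "outcome_unknown": _fails_outcome,
    "prehospital_rosc": _fails_rosc,
    "kanto_region": _fails_region,
    "transition_year": _fails_transition,
}


def first_failed_filter(rec: UtsteinRecord) -> Optional[str]:
    """Name of the first funnel step the record fails, or None if eligible."""
    for step in FILTER_STEPS:
        if _PREDICATES[step](rec):
            return step
    return None


def apply_selection_filters(
    records: Iterable[UtsteinRecord],
) -> tuple[list[UtsteinRecord], ExclusionLog]:
    """Run the selection funnel, returning the cohort and the exclusion log."""
    log = ExclusionLog()
    cohort: list[UtsteinRecord] = []
    for rec in records:
        log.n_input += 1
        step = first_failed_filter(rec)
        if step is None:
            cohort.append(rec)
        else:
            log.tallies[step] += 1
    log.n_retained = len(cohort)
    log.check()
    return cohort, log
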