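"""Predicted-vs-observed probability table per score point.

Calibration compares a supplied predicted probability of CPC 1-2 at each
score against the proportion observed in the validation cohort, with a
binomial CI on the observed side.  The predicted values come from the user's
configuration (typically derivation-cohort rates); no recalibration is done.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .metrics import SCORES, StratumTable, observed_proportions_by_score


class CalibrationConfigError(ValueError):
    """A score occupied in the cohort has no predicted probability."""


@dataclass(frozen=True)
class CalibrationPoint:
    score: int
    predicted: float
    observed: float
    ci_low: float
    ci_high: float
    n: int


def calibration_table(
    table: StratumTable,
    predicted: Mapping[int, float],
    level: float = 0.95,
    ci_method: str = "clopper_pearson",
) -> list[CalibrationPoint]:
    """One calibration point per occupied score stratum."""
    for s in SCORES:
        if table.n[s] > 0 and s not in predicted:
            raise CalibrationConfigError(f"no predicted probability for score {s}")
    for s, p in predicted.items():
        if not 0.0 <= p <= 1.0:
            raise CalibrationConfigError(f"predicted probability for score {s} is {p}")
    points = []
    for prop in observed_proportions_by_score(table, level=level, ci_method=ci_method):
        if not prop.defined:
            continue
        points.append(
            CalibrationPoint(
                score=prop.score,
                predicted=float(predicted[prop.score]),
                observed=prop.proportion,
                ci_low=prop.ci[0],
                ci_high=prop.ci[1],
                n=prop.n,
            )
        )
    return points
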