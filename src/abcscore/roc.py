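"""ROC curve, tie-corrected AUROC, and Youden-index cutoff for the 0-3 score.

With only four score levels the ROC consists of the corners plus one point
per threshold in {1,2,3}, oriented so that 'score >= t' predicts the
favourable outcome.  The AUROC is computed two ways that must agree to
1e-12: the trapezoidal area over the five points, and the rank form

    AUROC = [ sum_{s>s'} pos_s * neg_s' + 1/2 sum_s pos_s * neg_s ] / (P * (N-P))

which gives half-credit to tied score pairs (the Mann-Whitney statistic of
an ordinal marker).  The optimal cutoff maximises the Youden index
J = sensitivity + specificity - 1, ties broken toward the larger (more
specific) threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .metrics import SCORES, THRESHOLDS, DegenerateTableError, StratumTable


@dataclass(frozen=True)
class ROCResult:
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), sorted by fpr
    auroc: float
    youden: tuple[tuple[int, float], ...]  # (threshold, J)
    optimal_threshold: int


def _rank_auroc(table: StratumTable) -> float:
    pos, neg = table.pos, table.neg
    P = sum(pos)
    Q = sum(neg)
    wins = sum(
        pos[s] * neg[t] for s in SCORES for t in SCORES if s > t
    )
    ties = sum(pos[s] * neg[s] for s in SCORES)
    return (wins + 0.5 * ties) / (P * Q)


def _trapezoid(points: list[tuple[float, float]]) -> float:
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


def roc_from_strata(table: StratumTable) -> ROCResult:
    """ROC points, tie-corrected AUROC and Youden cutoff for one group."""
    P = table.P
    Q = table.N - table.P
    if P == 0:
        raise DegenerateTableError("favourable (CPC 1-2) class is empty")
    if Q == 0:
        raise DegenerateTableError("unfavourable (CPC 3-5) class is empty")

    points: list[tuple[float, float]] = [(0.0, 0.0)]
    youden: list[tuple[int, float]] = []
    for t in sorted(THRESHOLDS, reverse=True):  # high threshold = low fpr
        tp = sum(table.pos[s] for s in SCORES if s >= t)
        fp = sum(table.n[s] - table.pos[s] for s in SCORES if s >= t)
        tpr, fpr = tp / P, fp / Q
        points.append((fpr, tpr))
        youden.append((t, tpr + (1 - fpr) - 1))
    points.append((1.0, 1.0))
    points.sort()

    area = _trapezoid(points)
    rank = _rank_auroc(table)
    if not math.isclose(area, rank, abs_tol=1e-12):
        raise AssertionError(
            f"trapezoid ({area!r}) and rank ({rank!r}) AUROC disagree"
        )

    youden.sort()
    # max J; ties go to the larger threshold (fewer false positives)
    best = max(youden, key=lambda tj: (tj[1], tj[0]))[0]
    return ROCResult(
        points=tuple(points),
        auroc=rank,
        youden=tuple(youden),
        optimal_threshold=best,
    )


def youden_optimal(roc: ROCResult) -> int:
    """Threshold maximising J = sensitivity + specificity - 1."""
    if not roc.youden:
        raise ValueError("empty Youden list")
    return max(roc.youden, key=lambda tj: (tj[1], tj[0]))[0]


def auroc_ci_hanley_mcneil(
    table: StratumTable, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil interval for the AUROC (descriptive output only)."""
    auc = _rank_auroc(table)
    P = table.P
    Q = table.N - table.P
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (P - 1) * (q1 - auc**2) + (Q - 1) * (q2 - auc**2)) / (
        P * Q
    )
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)
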