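"""Score-stratum contingency tables and diagnostic test characteristics.

A validation cohort is summarised per guideline group as a 4x2 table: for
each ABC score s in {0,1,2,3}, the number of patients ``n_s`` and the number
with a favourable outcome (CPC 1-2) ``pos_s``.  Published validation reports
print the *cumulative* form instead - patient and favourable counts at the
thresholds score>=1, score>=2 and score=3 - and the stratum table is
recovered exactly as successive differences of those cumulative counts.

At a threshold t, a patient is test-positive when score >= t, giving the
usual 2x2 counts and sensitivity, specificity and likelihood ratios.
Binomial proportions carry Clopper-Pearson intervals by default (Wilson and
Wald are available); likelihood-ratio intervals use the delta method on the
log ratio (Simel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .records import GuidelineGroup, UtsteinRecord
from .score import ScoreResult

SCORES = (0, 1, 2, 3)
THRESHOLDS = (1, 2, 3)

_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson", "wald": "normal"}


class DegenerateTableError(ValueError):
    """A metric is undefined because one outcome class is empty."""


class InfiniteLikelihoodRatio(ZeroDivisionError):
    """LR+ is infinite (no false positives) or LR- undefined (no true negatives)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as clinical tables conventionally print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StratumTable:
    """Per-score patient and favourable-outcome counts for one group."""

    group: Optional[GuidelineGroup]
    n: tuple[int, int, int, int]
    pos: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for s in SCORES:
            if not 0 <= self.pos[s] <= self.n[s]:
                raise ValueError(
                    f"score {s}: need 0 <= pos ({self.pos[s]}) <= n ({self.n[s]})"
                )

    @property
    def N(self) -> int:
        return sum(self.n)

    @property
    def P(self) -> int:
        return sum(self.pos)

    @property
    def neg(self) -> tuple[int, int, int, int]:
        return tuple(self.n[s] - self.pos[s] for s in SCORES)


@dataclass(frozen=True)
class CumulativeStrata:
    """Counts at the thresholds score>=1, score>=2, score=3, plus totals."""

    N: int
    P: int
    n_ge: tuple[int, int, int]  # n at >=1, >=2, =3
    pos_ge: tuple[int, int, int]

    def __post_init__(self) -> None:
        n1, n2, n3 = self.n_ge
        p1, p2, p3 = self.pos_ge
        if not (self.N >= n1 >= n2 >= n3 >= 0):
            raise ValueError(f"patient counts not monotone: N={self.N}, {self.n_ge}")
        if not (self.P >= p1 >= p2 >= p3 >= 0):
            raise ValueError(f"favourable counts not monotone: P={self.P}, {self.pos_ge}")
        for nt, pt in zip(self.n_ge, self.pos_ge):
            if pt > nt:
                raise ValueError(f"favourable count {pt} exceeds patient count {nt}")


def strata_from_cumulative(
    cum: CumulativeStrata, group: Optional[GuidelineGroup] = None
) -> StratumTable:
    """Recover the per-score table by successive differences."""
    n1, n2, n3 = cum.n_ge
    p1, p2, p3 = cum.pos_ge
    return StratumTable(
        group=group,
        n=(cum.N - n1, n1 - n2, n2 - n3, n3),
        pos=(cum.P - p1, p1 - p2, p2 - p3, p3),
    )


def cumulative_from_strata(table: StratumTable) -> CumulativeStrata:
    """Forward direction of the strata <-> cumulative round trip."""
    n, pos = table.n, table.pos
    return CumulativeStrata(
        N=table.N,
        P=table.P,
        n_ge=(n[1] + n[2] + n[3], n[2] + n[3], n[3]),
        pos_ge=(pos[1] + pos[2] + pos[3], pos[2] + pos[3], pos[3]),
    )


def build_stratum_table(
    scored_cohort: Iterable[tuple[UtsteinRecord, ScoreResult]],
    group: Optional[GuidelineGroup] = None,
) -> StratumTable:
    """Tally a scored, outcome-labelled cohort into the per-score table.

    Records are restricted to ``group`` when one is given; a record with an
    unknown CPC raises (the selection funnel removes those upstream).
    """
    n = [0, 0, 0, 0]
    pos = [0, 0, 0, 0]
    for rec, score in scored_cohort:
        if group is not None and rec.guideline_group.label is not group.label:
            continue
        if not rec.cpc.is_known:
            raise ValueError(f"record {rec.record_id}: outcome unknown")
        s = score.total
        n[s] += 1
        if rec.cpc.favourable:
            pos[s] += 1
    return StratumTable(group=group, n=tuple(n), pos=tuple(pos))


# ---------------------------------------------------------------------------
# confidence intervals


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "clopper_pearson"
) -> tuple[float, float]:
    """Binomial CI for a proportion k/n; Clopper-Pearson exact by default."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    try:
        sm_method = _CI_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}"
        ) from None
    low, high = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    return max(0.0, float(low)), min(1.0, float(high))


def lr_ci(
    tp: int, fp: int, fn: int, tn: int, level: float = 0.95
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Simel log-method CIs for the positive and negative likelihood ratios.

    ``exp(ln LR +/- z * SE)`` with ``SE^2 = 1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)``
    for LR+ (and the fn/tn analogue for LR-).  A zero cell that would make a
    ratio infinite raises rather than overflowing.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2)
    P, Q = tp + fn, fp + tn
    if P == 0 or Q == 0:
        raise DegenerateTableError("both outcome classes must be non-empty")
    if fp == 0:
        raise InfiniteLikelihoodRatio("LR+ is infinite (fp = 0); no finite interval")
    if tn == 0:
        raise InfiniteLikelihoodRatio("LR- is undefined (specificity = 0)")
    sens, spec = tp / P, tn / Q
    lr_pos = sens / (1 - spec)
    if tp == 0:
        pos_interval = (0.0, 0.0)  # point LR+ = 0; log interval degenerate
    else:
        se_pos = math.sqrt(1 / tp - 1 / P + 1 / fp - 1 / Q)
        pos_interval = (
            lr_pos * math.exp(-z * se_pos),
            lr_pos * math.exp(z * se_pos),
        )
    lr_neg = (1 - sens) / spec
    if fn == 0:
        neg_interval = (0.0, 0.0)
    else:
        se_neg = math.sqrt(1 / fn - 1 / P + 1 / tn - 1 / Q)
        neg_interval = (
            lr_neg * math.exp(-z * se_neg),
            lr_neg * math.exp(z * se_neg),
        )
    return pos_interval, neg_interval


# ---------------------------------------------------------------------------
# test characteristics


@dataclass(frozen=True)
class Estimate:
    point: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity/LRs of 'score >= threshold' for CPC 1-2."""

    threshold: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Estimate
    specificity: Estimate
    lr_positive: Estimate
    lr_negative: Estimate


def characteristics_at_threshold(
    table: StratumTable,
    threshold: int,
    level: float = 0.95,
    ci_method: str = "clopper_pearson",
) -> TestCharacteristics:
    """2x2 test characteristics of the rule 'positive iff score >= threshold'."""
    if threshold not in THRESHOLDS:
        raise ValueError(f"threshold must be one of {THRESHOLDS}")
    P, N = table.P, table.N
    if P == 0 or N - P == 0:
        raise DegenerateTableError(
            "favourable class empty" if P == 0 else "unfavourable class empty"
        )
    tp = sum(table.pos[s] for s in SCORES if s >= threshold)
    pred_pos = sum(table.n[s] for s in SCORES if s >= threshold)
    fp = pred_pos - tp
    fn = P - tp
    tn = (N - P) - fp
    sens, spec = tp / P, tn / (N - P)
    (lp_lo, lp_hi), (ln_lo, ln_hi) = lr_ci(tp, fp, fn, tn, level=level)
    return TestCharacteristics(
        threshold=threshold,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=Estimate(sens, *proportion_ci(tp, P, level, ci_method)),
        specificity=Estimate(spec, *proportion_ci(tn, N - P, level, ci_method)),
        lr_positive=Estimate(sens / (1 - spec), lp_lo, lp_hi),
        lr_negative=Estimate((1 - sens) / spec, ln_lo, ln_hi),
    )


@dataclass(frozen=True)
class ScoreProportion:
    score: int
    n: int
    pos: int
    proportion: Optional[float]
    ci: Optional[tuple[float, float]]

    @property
    def defined(self) -> bool:
        return self.proportion is not None


def observed_proportions_by_score(
    table: StratumTable, level: float = 0.95, ci_method: str = "clopper_pearson"
) -> list[ScoreProportion]:
    """Observed CPC 1-2 proportion with CI at each score; empty strata flagged."""
    out = []
    for s in SCORES:
        if table.n[s] == 0:
            out.append(ScoreProportion(s, 0, 0, None, None))
        else:
            out.append(
                ScoreProportion(
                    score=s,
                    n=table.n[s],
                    pos=table.pos[s],
                    proportion=table.pos[s] / table.n[s],
                    ci=proportion_ci(table.pos[s], table.n[s], level, ci_method),
                )
            )
    return out
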