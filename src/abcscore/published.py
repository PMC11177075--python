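"""Published validation counts of the ABC score in the All-Japan Utstein Registry.

The nationwide external validation of the score reports, for each guideline
group (2005, 2010, 2015), the cohort size, the total number of CPC 1-2
outcomes, and patient / CPC 1-2 counts at the cumulative thresholds
score >= 1, score >= 2 and score = 3.  These cumulative counts determine the
full per-score contingency table by successive differences
(:func:`abcscore.metrics.strata_from_cumulative`), and the recovered stratum
sizes cross-check exactly against the independently printed per-score
patient counts, recorded here as ``PUBLISHED_STRATUM_N``.
"""

from __future__ import annotations

from .metrics import CumulativeStrata, StratumTable, strata_from_cumulative
from .records import GuidelineGroup, GuidelineLabel

PUBLISHED_CUMULATIVE: dict[GuidelineLabel, CumulativeStrata] = {
    GuidelineLabel.G2005: CumulativeStrata(
        N=162_710, P=1_161, n_ge=(75_236, 16_633, 2_705), pos_ge=(1_004, 666, 258)
    ),
    GuidelineLabel.G2010: CumulativeStrata(
        N=186_228, P=1_420, n_ge=(80_617, 16_290, 2_315), pos_ge=(1_266, 811, 309)
    ),
    GuidelineLabel.G2015: CumulativeStrata(
        N=190_794, P=1_801, n_ge=(81_144, 15_978, 2_364), pos_ge=(1_614, 1_029, 396)
    ),
}

#: Independently printed per-score patient counts (scores 0,1,2,3).
PUBLISHED_STRATUM_N: dict[GuidelineLabel, tuple[int, int, int, int]] = {
    GuidelineLabel.G2005: (87_474, 58_603, 13_928, 2_705),
    GuidelineLabel.G2010: (105_611, 64_327, 13_975, 2_315),
    GuidelineLabel.G2015: (109_650, 65_166, 13_614, 2_364),
}


def _group(label: GuidelineLabel) -> GuidelineGroup:
    from .records import GUIDELINE_YEARS

    return GuidelineGroup(label, GUIDELINE_YEARS[label])


def published_stratum_table(label: GuidelineLabel) -> StratumTable:
    """Per-score contingency table reconstructed from the published counts."""
    return strata_from_cumulative(PUBLISHED_CUMULATIVE[label], group=_group(label))


def all_published_tables() -> dict[GuidelineLabel, StratumTable]:
    return {
        label: published_stratum_table(label) for label in PUBLISHED_CUMULATIVE
    }
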