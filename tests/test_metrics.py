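"""Stratum tables, cumulative reconstruction, and test characteristics."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import binom

from abcscore import (
    Cpc,
    CumulativeStrata,
    GuidelineLabel,
    StratumTable,
    build_stratum_table,
    characteristics_at_threshold,
    cumulative_from_strata,
    lr_ci,
    observed_proportions_by_score,
    proportion_ci,
    strata_from_cumulative,
)
from abcscore.metrics import (
    DegenerateTableError,
    InfiniteLikelihoodRatio,
    round_half_up,
)
from abcscore.score import ScoreResult

from conftest import make_record


def _scored(scores, cpcs):
    out = []
    for i, (s, cpc) in enumerate(zip(scores, cpcs)):
        rec = make_record(f"r{i}", cpc=Cpc(cpc))
        comps = [1] * s + [0] * (3 - s)
        out.append((rec, ScoreResult(*comps)))
    return out


def test_build_stratum_table_hand_count():
    table = build_stratum_table(_scored([0, 0, 1, 2, 3, 3], [5, 2, 5, 1, 1, 5]))
    assert table.n == (2, 1, 1, 2)
    assert table.pos == (1, 0, 1, 1)


def test_build_stratum_table_empty_and_unknown_outcome():
    assert build_stratum_table([]).n == (0, 0, 0, 0)
    with pytest.raises(ValueError, match="unknown"):
        build_stratum_table(
            [(make_record(cpc=Cpc.UNKNOWN), ScoreResult(0, 0, 0))]
        )


def test_reconstruction_recovers_2005_strata(published_tables):
    """Successive differences of the cumulative threshold counts give the
    per-score strata, and the favourable counts sum to the group total."""
    t = published_tables[GuidelineLabel.G2005]
    assert t.n == (87_474, 58_603, 13_928, 2_705)
    assert t.pos == (157, 338, 408, 258)
    assert t.P == 1_161 and t.N == 162_710


def test_reconstruction_degenerate_all_mass_at_three():
    cum = CumulativeStrata(N=7, P=7, n_ge=(7, 7, 7), pos_ge=(7, 7, 7))
    t = strata_from_cumulative(cum)
    assert t.n == (0, 0, 0, 7) and t.pos == (0, 0, 0, 7)


def test_cumulative_monotonicity_violation_rejected():
    with pytest.raises(ValueError, match="monotone"):
        CumulativeStrata(N=10, P=5, n_ge=(3, 4, 2), pos_ge=(3, 2, 1))


@st.composite
def stratum_tables(draw):
    n = tuple(draw(st.integers(0, 50)) for _ in range(4))
    pos = tuple(draw(st.integers(0, n_s)) for n_s in n)
    return StratumTable(group=None, n=n, pos=pos)


@settings(deadline=None, derandomize=True)
@given(stratum_tables())
def test_strata_cumulative_round_trip(table):
    assert strata_from_cumulative(cumulative_from_strata(table)) == table


@settings(deadline=None, derandomize=True)
@given(stratum_tables())
def test_threshold_monotonicity_and_identities(table):
    """Sensitivity is non-increasing and specificity non-decreasing in the
    threshold; 2x2 counts always sum to N and the LR identities hold."""
    if table.P == 0 or table.N == table.P:
        with pytest.raises(DegenerateTableError):
            characteristics_at_threshold(table, 1)
        return
    prev_sens, prev_spec = math.inf, -math.inf
    for t in (1, 2, 3):
        try:
            ch = characteristics_at_threshold(table, t)
        except InfiniteLikelihoodRatio:
            # fp = 0: specificity is 1 at this and all higher thresholds
            break
        assert ch.tp + ch.fp + ch.fn + ch.tn == table.N
        sens, spec = ch.sensitivity.point, ch.specificity.point
        assert sens <= prev_sens + 1e-12
        assert spec >= prev_spec - 1e-12
        if spec < 1:
            assert math.isclose(ch.lr_positive.point, sens / (1 - spec), rel_tol=1e-12)
        if spec > 0:
            assert math.isclose(ch.lr_negative.point, (1 - sens) / spec, rel_tol=1e-12)
        prev_sens, prev_spec = sens, spec


TABLE2 = {
    # group -> threshold -> (sens %, spec %, LR+, LR-), printed at 2 d.p.
    GuidelineLabel.G2005: {
        1: (86.48, 54.05, 1.88, 0.25),
        2: (57.36, 90.12, 5.80, 0.47),
        3: (22.22, 98.49, 14.67, 0.79),
    },
    GuidelineLabel.G2010: {
        1: (89.15, 57.06, 2.08, 0.19),
        2: (57.11, 91.62, 6.82, 0.47),
        3: (21.76, 98.91, 20.05, 0.79),
    },
    GuidelineLabel.G2015: {
        1: (89.62, 57.92, 2.13, 0.18),
        2: (57.13, 92.09, 7.22, 0.47),
        3: (21.99, 98.96, 21.12, 0.79),
    },
}


@pytest.mark.parametrize("label", list(TABLE2))
@pytest.mark.parametrize("threshold", [1, 2, 3])
def test_published_test_characteristics(published_tables, label, threshold):
    """Reconstructed tables reproduce the published sensitivity, specificity
    and likelihood ratios at every threshold, to the printed 2 d.p."""
    ch = characteristics_at_threshold(published_tables[label], threshold)
    sens, spec, lrp, lrn = TABLE2[label][threshold]
    assert round_half_up(100 * ch.sensitivity.point) == sens
    assert round_half_up(100 * ch.specificity.point) == spec
    assert round_half_up(ch.lr_positive.point) == lrp
    assert round_half_up(ch.lr_negative.point) == lrn


def test_perfect_separation_characteristics():
    table = StratumTable(group=None, n=(10, 0, 0, 8), pos=(0, 0, 0, 5))
    ch = characteristics_at_threshold(table, 3)
    assert ch.sensitivity.point == 1.0
    assert ch.lr_negative.point == 0.0


def test_uninformative_test_has_lr_one():
    table = StratumTable(group=None, n=(10, 0, 0, 10), pos=(5, 0, 0, 5))
    ch = characteristics_at_threshold(table, 3)
    assert math.isclose(ch.lr_positive.point, 1.0)
    assert math.isclose(ch.lr_negative.point, 1.0)


def test_infinite_lr_signalled_explicitly():
    table = StratumTable(group=None, n=(10, 0, 0, 5), pos=(2, 0, 0, 5))
    with pytest.raises(InfiniteLikelihoodRatio):
        characteristics_at_threshold(table, 3)


# -- proportion CIs ---------------------------------------------------------


def clopper_pearson_bisection(k, n, level=0.95):
    """Independent oracle: root-find the binomial tail probabilities.

    The lower bound solves P(X >= k | p) = alpha/2 and the upper bound
    P(X <= k | p) = alpha/2, the defining equations of the exact interval.
    """
    alpha = 1 - level
    low = (
        0.0
        if k == 0
        else brentq(lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-15, k / n)
    )
    high = (
        1.0
        if k == n
        else brentq(lambda p: binom.cdf(k, n, p) - alpha / 2, k / n, 1 - 1e-15)
    )
    return low, high


@pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (3, 17), (258, 2705), (157, 87474)])
def test_clopper_pearson_matches_tail_bisection(k, n):
    low, high = proportion_ci(k, n)
    o_low, o_high = clopper_pearson_bisection(k, n)
    assert low == pytest.approx(o_low, abs=1e-7)
    assert high == pytest.approx(o_high, abs=1e-7)
    assert 0.0 <= low <= k / n <= high <= 1.0
    if k == 0:
        assert low == 0.0
    if k == n:
        assert high == 1.0


def test_proportion_ci_alternative_methods_and_errors():
    for method in ("wilson", "wald"):
        low, high = proportion_ci(30, 100, method=method)
        assert low < 0.3 < high
    with pytest.raises(ValueError):
        proportion_ci(1, 0)
    with pytest.raises(ValueError, match="method"):
        proportion_ci(1, 10, method="bayes")


def test_published_score3_proportion_within_half_point(published_tables):
    """258/2705 = 9.54% with a CP interval within 0.5 points of the printed
    (8.46, 10.71) band, whose original method is unstated."""
    t = published_tables[GuidelineLabel.G2005]
    props = observed_proportions_by_score(t)
    p3 = props[3]
    assert round_half_up(100 * p3.proportion) == 9.54
    assert 100 * p3.ci[0] == pytest.approx(8.46, abs=0.5)
    assert 100 * p3.ci[1] == pytest.approx(10.71, abs=0.5)


def test_observed_proportions_flag_empty_strata():
    table = StratumTable(group=None, n=(5, 0, 0, 2), pos=(0, 0, 0, 1))
    props = observed_proportions_by_score(table)
    assert props[1].defined is False and props[1].ci is None
    assert props[0].proportion == 0.0


# -- likelihood-ratio CIs ----------------------------------------------------


def test_lr_points_match_published_counts():
    # 2005 group, threshold 3
    (lo, hi), _ = lr_ci(tp=258, fp=2_447, fn=903, tn=159_102)
    lrp = (258 / 1161) / (2447 / 161549)
    assert round_half_up(lrp) == 14.67
    assert lo < lrp < hi
    # log-method interval is in the right neighbourhood of the printed one
    assert lo == pytest.approx(13.08, abs=0.5)
    assert hi == pytest.approx(16.45, abs=0.5)


def test_lr_ci_zero_fp_is_explicit_error():
    with pytest.raises(InfiniteLikelihoodRatio):
        lr_ci(tp=5, fp=0, fn=5, tn=10)
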