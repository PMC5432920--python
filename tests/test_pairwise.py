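"""Pairwise association: contingency tables, signed Yates chi-square, AC index.

The exhaustive checks enumerate every 2x2 table with N <= 12 and compare
against independent oracles: scipy's continuity-corrected chi-square for the
magnitude, and an exact-rational evaluation of the piecewise AC rules.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import standassoc as sa
from standassoc.stemmap import PresenceMatrix


def all_tables(max_n=12, min_n=2):
    for n in range(min_n, max_n + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield sa.ContingencyTable(a, b, c, n - a - b - c)


def ac_oracle(t):
    """Exact-rational AC: the three piecewise branch rules applied verbatim."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if a * d >= b * c:
        den = (a + b) * (b + d)
    elif d >= a:
        den = (a + b) * (a + c)
    else:
        den = (b + d) * (c + d)
    return None if den == 0 else Fraction(a * d - b * c, den)


# --- contingency construction ---------------------------------------------

def test_contingency_exhaustive_two_bit_case():
    t = sa.contingency([1, 1, 0, 0], [1, 0, 1, 0])
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_contingency_identical_vectors():
    t = sa.contingency([1, 0, 1, 0], [1, 0, 1, 0])
    assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)


@given(
    va=st.lists(st.integers(0, 1), min_size=50, max_size=50),
    vb=st.lists(st.integers(0, 1), min_size=50, max_size=50),
)
@settings(max_examples=50, derandomize=True)
def test_contingency_cells_sum_to_n(va, vb):
    t = sa.contingency(va, vb)
    assert t.N == 50
    assert t.a + t.b == sum(va) and t.a + t.c == sum(vb)


@pytest.mark.parametrize(
    "va,vb",
    [([1, 0], [1, 0, 1]), ([1, 2, 0], [1, 0, 0]), ([1], [0])],
)
def test_contingency_rejects_bad_vectors(va, vb):
    with pytest.raises(ValueError):
        sa.contingency(va, vb)


# --- Yates chi-square ------------------------------------------------------

def test_yates_worked_example():
    # |ad-bc| = 275, correction 25 -> 250; 50*250^2/(15*35*15*35)
    t = sa.ContingencyTable(10, 5, 5, 30)
    assert sa.yates_chi2(t) == pytest.approx(11.338, abs=5e-4)
    assert sa.yates_chi2(t) > 0


def test_yates_zero_at_independence():
    assert sa.yates_chi2(sa.ContingencyTable(2, 2, 2, 2)) == 0.0


def test_yates_magnitude_symmetric_in_off_diagonal():
    t1 = sa.ContingencyTable(10, 7, 2, 30)
    t2 = sa.ContingencyTable(10, 2, 7, 30)
    assert abs(sa.yates_chi2(t1)) == pytest.approx(abs(sa.yates_chi2(t2)))


def test_yates_undefined_on_zero_margin():
    val = sa.yates_chi2(sa.ContingencyTable(0, 0, 3, 4))
    assert math.isnan(val)
    assert sa.classify_chi2(val) == "undefined"


def test_yates_sign_follows_cross_product():
    assert sa.yates_chi2(sa.ContingencyTable(10, 2, 2, 10)) > 0
    assert sa.yates_chi2(sa.ContingencyTable(2, 10, 10, 2)) < 0


# --- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "chi2,expected",
    [
        (6.88, "extra_positive"),
        (-4.02, "negative"),
        (4.52, "positive"),
        (3.840999, "none"),
        (-3.840999, "none"),
        (-6.88, "extra_negative"),
        (0.0, "none"),
    ],
)
def test_classify_chi2_five_bands(chi2, expected):
    assert sa.classify_chi2(chi2) == expected


def test_thresholds_are_chi2_df1_quantiles():
    lo, hi = sa.chi2_thresholds()
    assert lo == pytest.approx(3.841, abs=1e-3)
    assert hi == pytest.approx(6.635, abs=1e-3)


# --- AC coefficient --------------------------------------------------------

def test_ac_complete_positive_and_negative():
    assert sa.association_coefficient(sa.ContingencyTable(7, 0, 0, 13)) == 1.0
    assert sa.association_coefficient(sa.ContingencyTable(0, 3, 4, 0)) == -1.0


def test_ac_branch_examples():
    # first branch: ad >= bc
    assert sa.association_coefficient(sa.ContingencyTable(10, 5, 5, 30)) == pytest.approx(
        275 / 525
    )
    # third branch: ad < bc and d < a
    assert sa.association_coefficient(sa.ContingencyTable(5, 4, 3, 2)) == pytest.approx(
        -2 / 30
    )


def test_ac_second_branch():
    # ad = 2 < bc = 12, d = 4 >= a = 1 -> (ad-bc)/((a+b)(a+c))
    t = sa.ContingencyTable(1, 3, 4, 2)
    assert sa.association_coefficient(t) == pytest.approx((2 - 12) / (4 * 5))


def test_ac_undefined_when_branch_denominator_vanishes():
    assert math.isnan(sa.association_coefficient(sa.ContingencyTable(0, 0, 0, 5)))


# --- exhaustive oracle equivalence ----------------------------------------

def test_chi2_matches_scipy_over_all_small_tables():
    """Signed magnitude vs scipy's Yates-corrected statistic, every 2x2
    table with N <= 12 and no zero margin."""
    checked = 0
    for t in all_tables():
        if t.degenerate:
            assert math.isnan(sa.yates_chi2(t))
            continue
        stat = chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=True
        ).statistic
        got = sa.yates_chi2(t)
        assert abs(got) == pytest.approx(stat, abs=1e-12), (t.a, t.b, t.c, t.d)
        cross = t.a * t.d - t.b * t.c
        assert math.copysign(1, got) == math.copysign(1, cross) or got == cross == 0
        checked += 1
    assert checked > 100


def test_ac_matches_rational_oracle_and_is_bounded():
    for t in all_tables():
        expected = ac_oracle(t)
        got = sa.association_coefficient(t)
        if expected is None:
            assert math.isnan(got)
            continue
        assert got == pytest.approx(float(expected), abs=1e-12)
        assert -1 <= expected <= 1
        # sign coherence with the cross product
        cross = t.a * t.d - t.b * t.c
        assert (expected > 0) == (cross > 0) and (expected < 0) == (cross < 0)


# --- all-pairs analysis ----------------------------------------------------

def _random_pm(n_species=11, n_quadrats=50, seed=0):
    rng = np.random.default_rng(seed)
    m = (rng.uniform(size=(n_species, n_quadrats)) < 0.45).astype(int)
    labels = [f"S{i:02d}" for i in range(n_species)]
    return PresenceMatrix(species_labels=labels, matrix=m, mode="presence")


def test_pairwise_enumerates_all_pairs():
    pm = _random_pm()
    results, summary = sa.pairwise_analysis(pm)
    assert len(results) == 55
    assert summary.n_pairs == 55
    assert (
        summary.n_positive + summary.n_negative + summary.n_none + summary.n_undefined
        == 55
    )


def test_pairwise_shares_over_defined_pairs():
    s = sa.PairwiseSummary(
        n_pairs=55, n_positive=21, n_negative=31, n_none=3, n_undefined=0
    )
    assert s.share("positive") == pytest.approx(38.18, abs=0.005)
    assert s.share("negative") == pytest.approx(56.36, abs=0.005)
    assert s.share("none") == pytest.approx(5.45, abs=0.005)


def test_all_zero_species_row_flagged_undefined():
    pm = _random_pm()
    pm.matrix[3] = 0
    results, summary = sa.pairwise_analysis(pm)
    undefined = [r for r in results if not r.defined]
    assert len(undefined) == 10
    assert all("S03" in (r.species_a, r.species_b) for r in undefined)
    assert summary.n_undefined == 10
    assert summary.n_defined == 45


def test_pair_association_is_order_independent():
    pm = _random_pm(seed=5)
    r1 = sa.pair_association(pm, "S01", "S07")
    r2 = sa.pair_association(pm, "S07", "S01")
    assert r1 == r2


def test_results_frame_and_semi_matrix_round_trip():
    pm = _random_pm(n_species=4, seed=9)
    results, _ = sa.pairwise_analysis(pm)
    frame = sa.results_to_frame(results)
    assert len(frame) == 6
    mat = sa.semi_matrix(results, pm.species_labels, value="chi2_signed")
    r = results[0]
    assert mat.loc[r.species_b, r.species_a] == r.chi2_signed
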