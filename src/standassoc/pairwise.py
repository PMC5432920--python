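"""Pairwise interspecific association: 2x2 tables, signed Yates chi-square, AC index.

For every unordered species pair the quadrat-level presence/absence vectors
are cross-tabulated into a 2x2 contingency table

              B present   B absent
  A present       a           b        m = a + b
  A absent        c           d        n = c + d
                r = a+c     s = b+d    N

and tested for independence with the continuity-corrected (Yates)
chi-square.  The statistic is reported *signed*: positive when ad > bc
(co-occurrence beyond chance), negative when ad < bc (segregation).  The
association coefficient AC in [-1, 1] quantifies strength with a piecewise
denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .stemmap import PresenceMatrix

Category = Literal[
    "extra_positive", "positive", "none", "negative", "extra_negative", "undefined"
]


def chi2_thresholds() -> tuple[float, float]:
    """Classification band edges: chi-square df=1 quantiles at cumulative
    0.95 (~3.841) and 0.99 (~6.635), computed at full precision."""
    return chi2_dist.ppf(0.95, 1), chi2_dist.ppf(0.99, 1)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 presence/absence cross-tabulation of one species pair."""

    a: int  # quadrats with both species
    b: int  # A only
    c: int  # B only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(m, n, r, s) = (a+b, c+d, a+c, b+d)."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @property
    def degenerate(self) -> bool:
        """True when any margin is zero: one species occupies every quadrat
        or none, and both the chi-square and AC denominators vanish."""
        return 0 in self.margins


def contingency(
    row_a: Sequence[int] | np.ndarray, row_b: Sequence[int] | np.ndarray
) -> ContingencyTable:
    """Cross-tabulate two equal-length 0/1 presence vectors."""
    va = np.asarray(row_a)
    vb = np.asarray(row_b)
    if va.shape != vb.shape or va.ndim != 1:
        raise ValueError("presence vectors must be 1-D and equal length")
    if va.size < 2:
        raise ValueError("need at least 2 quadrats")
    for v in (va, vb):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("presence vectors must be binary (0/1)")
    a = int(np.sum((va == 1) & (vb == 1)))
    b = int(np.sum((va == 1) & (vb == 0)))
    c = int(np.sum((va == 0) & (vb == 1)))
    d = int(np.sum((va == 0) & (vb == 0)))
    return ContingencyTable(a, b, c, d)


def yates_chi2(ct: ContingencyTable) -> float:
    """Signed continuity-corrected chi-square.

    Magnitude: N * (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)); the
    correction term is clamped at zero so near-null tables cannot inflate
    the statistic.  Sign: +1 if ad > bc, -1 if ad < bc, 0 at equality.
    NaN when any margin is zero (statistic undefined).
    """
    if ct.degenerate:
        return math.nan
    cross = ct.a * ct.d - ct.b * ct.c
    if cross == 0:
        return 0.0
    corrected = max(abs(cross) - ct.N / 2.0, 0.0)
    m, n, r, s = ct.margins
    magnitude = ct.N * corrected**2 / (m * n * r * s)
    return math.copysign(magnitude, cross)


def classify_chi2(
    chi2_signed: float, thresholds: tuple[float, float] | None = None
) -> Category:
    """Five-level association category from the signed chi-square.

    |chi2| below the 95 % quantile: no association; between the 95 % and
    99 % quantiles: significant positive/negative by sign; at or above the
    99 % quantile: extra-significant positive/negative.
    """
    if math.isnan(chi2_signed):
        return "undefined"
    lo, hi = thresholds if thresholds is not None else chi2_thresholds()
    mag = abs(chi2_signed)
    if mag < lo:
        return "none"
    if mag < hi:
        return "positive" if chi2_signed > 0 else "negative"
    return "extra_positive" if chi2_signed > 0 else "extra_negative"


def association_coefficient(ct: ContingencyTable) -> float:
    """AC association coefficient in [-1, 1].

    Piecewise denominator:
      ad >= bc:          (ad - bc) / ((a+b)(b+d))
      ad < bc, d >= a:   (ad - bc) / ((a+b)(a+c))
      ad < bc, d < a:    (ad - bc) / ((b+d)(c+d))

    Reaches exactly +1 for complete positive association (b = c = 0) and
    -1 for complete negative association (a = d = 0).  NaN when the chosen
    branch's denominator is zero.
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    cross = a * d - b * c
    if cross >= 0:
        denom = (a + b) * (b + d)
    elif d >= a:
        denom = (a + b) * (a + c)
    else:
        denom = (b + d) * (c + d)
    if denom == 0:
        return math.nan
    return cross / denom


@dataclass(frozen=True)
class PairAssociationResult:
    species_a: str
    species_b: str
    table: ContingencyTable
    chi2_signed: float
    ac: float
    category: Category

    @property
    def defined(self) -> bool:
        return self.category != "undefined"

    @property
    def chi2_magnitude(self) -> float:
        return abs(self.chi2_signed)


@dataclass
class PairwiseSummary:
    """Counts and shares of association directions over all species pairs.

    Shares (percent) are taken over *defined* pairs only; pairs whose
    contingency table has a zero margin are tallied separately.
    """

    n_pairs: int
    n_positive: int
    n_negative: int
    n_none: int
    n_undefined: int

    @property
    def n_defined(self) -> int:
        return self.n_pairs - self.n_undefined

    def share(self, which: str) -> float:
        count = {
            "positive": self.n_positive,
            "negative": self.n_negative,
            "none": self.n_none,
        }[which]
        return count / self.n_defined * 100 if self.n_defined else math.nan


def pair_association(
    pm: PresenceMatrix, species_a: str, species_b: str
) -> PairAssociationResult:
    """Association result for one unordered species pair.

    The AC denominator depends on which species plays the "A" role in the
    contingency table, so the roles are canonicalised (A = lexicographically
    smaller label) and the result is independent of argument order.  The
    chi-square and category are role-symmetric anyway.
    """
    sa, sb = sorted((species_a, species_b))
    ct = contingency(pm.to_presence().row(sa), pm.to_presence().row(sb))
    chi2 = yates_chi2(ct)
    return PairAssociationResult(
        sa, sb, ct, chi2, association_coefficient(ct), classify_chi2(chi2)
    )


def pairwise_analysis(
    pm: PresenceMatrix, species: Sequence[str] | None = None
) -> tuple[list[PairAssociationResult], PairwiseSummary]:
    """Evaluate all C(k, 2) unordered species pairs of a presence matrix.

    Direction is the sign of the signed chi-square (equivalently of
    ad - bc); 'none' pairs have ad = bc exactly.  Pair roles are
    canonicalised as in `pair_association`.
    """
    pm = pm.to_presence()
    labels = list(species) if species is not None else list(pm.species_labels)
    if len(labels) < 2:
        raise ValueError("pairwise analysis needs at least 2 species")
    results: list[PairAssociationResult] = []
    n_pos = n_neg = n_none = n_undef = 0
    for sa, sb in itertools.combinations(labels, 2):
        sa, sb = sorted((sa, sb))
        ct = contingency(pm.row(sa), pm.row(sb))
        chi2 = yates_chi2(ct)
        ac = association_coefficient(ct)
        category = classify_chi2(chi2)
        results.append(PairAssociationResult(sa, sb, ct, chi2, ac, category))
        if category == "undefined":
            n_undef += 1
        else:
            cross = ct.a * ct.d - ct.b * ct.c
            if cross > 0:
                n_pos += 1
            elif cross < 0:
                n_neg += 1
            else:
                n_none += 1
    summary = PairwiseSummary(
        n_pairs=len(results),
        n_positive=n_pos,
        n_negative=n_neg,
        n_none=n_none,
        n_undefined=n_undef,
    )
    return results, summary


def results_to_frame(results: Sequence[PairAssociationResult]) -> pd.DataFrame:
    """Long-format table of pairwise results (one row per unordered pair)."""
    return pd.DataFrame(
        {
            "species_a": [r.species_a for r in results],
            "species_b": [r.species_b for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "chi2_signed": [r.chi2_signed for r in results],
            "ac": [r.ac for r in results],
            "category": [r.category for r in results],
        }
    )


def semi_matrix(
    results: Sequence[PairAssociationResult],
    species: Sequence[str],
    value: Literal["chi2_signed", "ac", "category"] = "chi2_signed",
) -> pd.DataFrame:
    """Lower-triangular species x species matrix of one pairwise quantity."""
    idx = {s: i for i, s in enumerate(species)}
    mat = pd.DataFrame(
        np.full((len(species), len(species)), np.nan, dtype=object),
        index=list(species),
        columns=list(species),
    )
    for r in results:
        i, j = idx[r.species_a], idx[r.species_b]
        lo, hi = (r.species_a, r.species_b) if i > j else (r.species_b, r.species_a)
        mat.loc[lo, hi] = getattr(r, value) if value != "category" else r.category
    return mat
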