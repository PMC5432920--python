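"""Overall multi-species association: Schluter's variance-ratio test.

The variance ratio V compares the variance of quadrat species-richness
totals T_j with the sum of the per-species occupancy variances:

    V = S_T^2 / sum_i delta_i^2,
    S_T^2      = (1/N) sum_j (T_j - t)^2,
    delta_i^2  = (1/N) sum_j (X_ij - t_i)^2,

with N quadrats, X_ij the occurrence of species i in quadrat j, t_i its
mean and t the mean richness.  Under independence E[V] = 1; V > 1 indicates
net positive covariation, V < 1 net negative.  The test statistic W = N * V
is referred to a chi-square distribution with df = N; values outside the
central 90 % band mean the departure from independence is significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .stemmap import PresenceMatrix

Verdict = Literal[
    "significant_positive",
    "nonsignificant_positive",
    "nonsignificant_negative",
    "significant_negative",
    "independent",
]


@dataclass(frozen=True)
class VarianceRatioResult:
    V: float
    S_T2: float
    delta_sum: float
    W: float
    N: int
    bounds: tuple[float, float]
    verdict: Verdict


def quadrat_totals(pm: PresenceMatrix) -> np.ndarray:
    """Per-quadrat totals T_j (species richness in presence mode)."""
    if pm.matrix.size == 0:
        raise ValueError("empty occurrence matrix")
    return pm.matrix.sum(axis=0)


def variance_ratio(pm: PresenceMatrix) -> tuple[float, float, float]:
    """(V, S_T^2, sum delta_i^2) for an occurrence matrix.

    Variances use the population (1/N) normalisation.  When every species is
    constant across quadrats the denominator vanishes and V is undefined.
    """
    X = np.asarray(pm.matrix, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("variance ratio needs at least 2 quadrats")
    T = X.sum(axis=0)
    s_t2 = float(np.mean((T - T.mean()) ** 2))
    delta_sum = float(np.sum(np.mean((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1)))
    if delta_sum == 0.0:
        raise ValueError(
            "sum of per-species variances is zero (every species constant "
            "across quadrats); variance ratio undefined"
        )
    return s_t2 / delta_sum, s_t2, delta_sum


def w_statistic(V: float, N: int) -> float:
    """Schluter's test statistic W = N * V."""
    return N * V


def chisq_bounds(N: int, two_sided_level: float = 0.10) -> tuple[float, float]:
    """Central chi-square acceptance band for W at df = N.

    Returns quantiles at cumulative probabilities level/2 and 1 - level/2
    (default: the 5th and 95th percentiles, a two-sided 90 % band).
    """
    if not 0 < two_sided_level < 1:
        raise ValueError("two_sided_level must be in (0, 1)")
    return (
        float(chi2_dist.ppf(two_sided_level / 2, N)),
        float(chi2_dist.ppf(1 - two_sided_level / 2, N)),
    )


def overall_verdict(V: float, W: float, bounds: tuple[float, float]) -> Verdict:
    """Four-way verdict: direction from V vs 1, significance from W vs band."""
    lower, upper = bounds
    significant = W < lower or W > upper
    if V > 1:
        return "significant_positive" if significant else "nonsignificant_positive"
    if V < 1:
        return "significant_negative" if significant else "nonsignificant_negative"
    return "independent"


def overall_association(
    pm: PresenceMatrix, two_sided_level: float = 0.10
) -> VarianceRatioResult:
    """Run the full variance-ratio test on an occurrence matrix."""
    V, s_t2, delta_sum = variance_ratio(pm)
    N = pm.n_quadrats
    W = w_statistic(V, N)
    bounds = chisq_bounds(N, two_sided_level)
    return VarianceRatioResult(
        V=V,
        S_T2=s_t2,
        delta_sum=delta_sum,
        W=W,
        N=N,
        bounds=bounds,
        verdict=overall_verdict(V, W, bounds),
    )
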