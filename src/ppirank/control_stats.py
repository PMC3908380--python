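"""Negative-control statistics: rank-sum test and p-value -> FDR calibration.

The false-discovery calibration converts a single one-sided rank-sum
p-value into a lower bound on the posterior probability that the pair is a
null (non-specific) interaction, via the -e·p·ln(p) bound of Sellke,
Bayarri & Berger.  The bound is valid for p < 1/e and saturates at 0.5, so
per-pair FDR values always lie in (0, 0.5].  This is a per-pair
calibration, not a set-level multiple-testing procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import PairEvidence, ValidationError

#: Largest pooled sample size for which the exact enumeration is used.
EXACT_ENUMERATION_CAP = 12

#: p-values are floored here before taking the logarithm.
P_FLOOR = 1e-16


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of the one-sided Wilcoxon–Mann–Whitney comparison."""

    u_statistic: float
    p_value: float
    method: str  # "exact_enumeration" | "normal_tie_corrected"
    n_bait: int
    n_control: int


def _exact_enumeration_p(
    bait: Sequence[int], control: Sequence[int], alternative: str
) -> tuple[float, float]:
    """Exact permutation p for the rank-sum statistic with mid-ranks.

    Enumerates all C(n1+n2, n1) assignments of the pooled multiset to the
    bait group, so ties are handled exactly.  Returns (U, p).
    """
    pooled = np.asarray(list(bait) + list(control), dtype=float)
    n1 = len(bait)
    ranks = stats.rankdata(pooled)  # mid-ranks
    observed = float(ranks[:n1].sum())
    total = math.comb(len(pooled), n1)
    eps = 1e-9
    count = 0
    for idx in combinations(range(len(pooled)), n1):
        s = ranks[list(idx)].sum()
        if alternative == "greater":
            hit = s >= observed - eps
        elif alternative == "less":
            hit = s <= observed + eps
        else:  # two-sided: distance of rank-sum from its mean
            mu = n1 * (len(pooled) + 1) / 2.0
            hit = abs(s - mu) >= abs(observed - mu) - eps
        count += hit
    u = observed - n1 * (n1 + 1) / 2.0
    return u, count / total


def ranksum_p(
    bait_scs: Sequence[int],
    control_scs: Sequence[int],
    alternative: str = "greater",
    exact_cap: int = EXACT_ENUMERATION_CAP,
) -> RankSumResult:
    """One-sided rank-sum test of bait SCs against negative-control SCs.

    Compares the two populations "SCs of the prey in the bait purifications"
    vs "SCs of the prey in the negative controls", both zero-filled for
    non-detections.  The default alternative is that bait SCs are
    stochastically greater — enrichment over control is what marks a
    specific interactor.

    Uses exact enumeration over all group assignments of the pooled
    multiset when ``n1+n2 <= exact_cap`` (mid-ranks, so ties are exact);
    otherwise the normal approximation with tie and continuity correction.
    If every observation is equal the p-value is 1.
    """
    if len(bait_scs) == 0 or len(control_scs) == 0:
        raise ValidationError("rank-sum test requires non-empty bait and control vectors")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n1, n2 = len(bait_scs), len(control_scs)
    pooled = list(bait_scs) + list(control_scs)
    if len(set(pooled)) == 1:
        u = n1 * n2 / 2.0
        method = "exact_enumeration" if n1 + n2 <= exact_cap else "normal_tie_corrected"
        return RankSumResult(u, 1.0, method, n1, n2)
    if n1 + n2 <= exact_cap:
        u, p = _exact_enumeration_p(bait_scs, control_scs, alternative)
        return RankSumResult(u, p, "exact_enumeration", n1, n2)
    res = stats.mannwhitneyu(
        bait_scs, control_scs, alternative=alternative, method="asymptotic",
        use_continuity=True,
    )
    p = float(min(max(res.pvalue, P_FLOOR), 1.0))
    return RankSumResult(float(res.statistic), p, "normal_tie_corrected", n1, n2)


def fdr_from_p(p: float) -> float:
    """Calibrate a single p-value into a per-pair false discovery rate.

    For p < 1/e returns ``1 / (1 + (-e·p·ln p)^{-1})``; for p >= 1/e the
    bound is outside its validity region and the supremum 0.5 is returned.
    Monotone non-decreasing in p, with range (0, 0.5].
    """
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p-value must lie in (0, 1], got {p}")
    if p >= 1.0 / math.e:
        return 0.5
    p = max(p, P_FLOOR)
    bound = -math.e * p * math.log(p)  # in (0, 1) on this branch
    return bound / (1.0 + bound)


def fdr_for_pair(
    pair: PairEvidence,
    alternative: str = "greater",
    exact_cap: int = EXACT_ENUMERATION_CAP,
) -> float:
    """Rank-sum p-value of a pair's evidence, calibrated to an FDR."""
    if len(pair.sc_controls) == 0:
        raise ValidationError(
            "FDR computation requires negative controls: no control runs present"
        )
    result = ranksum_p(pair.sc_replicates, pair.sc_controls, alternative, exact_cap)
    return fdr_from_p(result.p_value)
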