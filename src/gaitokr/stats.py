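"""Nonparametric two-sample comparisons (Mann-Whitney U).

Animal-level measures are compared between genotype groups without assuming
normality.  The exact two-sided p is used whenever it is cheap and valid
(no ties, n1*n2 <= 64); otherwise the normal approximation with tie and
continuity corrections.  The method actually used is recorded on the result.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_MAX_PRODUCT = 64


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    n_a: int
    n_b: int
    u_statistic: float   # U of the first group, midrank ties
    p_value: float       # two-sided
    method: str          # "exact" | "normal-approx"


def mann_whitney_u(group_a, group_b, measure: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent samples.

    U is the rank-sum statistic of ``group_a`` with midrank tie handling;
    U(a,b) + U(b,a) = n_a * n_b always holds.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and a.size * b.size <= EXACT_MAX_PRODUCT:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal-approx"
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return GroupComparison(measure=measure, n_a=int(a.size), n_b=int(b.size),
                           u_statistic=float(res.statistic),
                           p_value=min(float(res.pvalue), 1.0), method=method)
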