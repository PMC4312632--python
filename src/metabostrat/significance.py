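"""Differential-metabolite calling by the dual significance criterion.

A feature is called differential when it passes BOTH:

1. the selection-frequency test — the upper-tail binomial probability of
   being chosen ``x`` or more times in ``n`` independent GA runs if features
   were picked at random with per-run probability ``m/v``:
   ``P(x) = sum_{i=x}^{n} C(n, i) (m/v)^i (1 - m/v)^(n-i)``, at P < 0.001;
2. the univariate Wilcoxon rank-sum (Mann-Whitney) test between the two
   classes, at P < 0.05.

No multiple-testing correction is applied beyond the stringent first
threshold.  ``m`` is the mean number of features selected per run, rounded
to an integer, so ``m/v`` is the per-feature per-run selection probability
under the null of undirected selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .ga import SelectionCounts

__all__ = [
    "DifferentialCall",
    "binomial_selection_pvalue",
    "wilcoxon_rank_sum",
    "call_differentials",
    "EXACT_ENUMERATION_LIMIT",
]

# combined group size at or below which the Wilcoxon P comes from full
# permutation enumeration (handles ties exactly); above it, the midrank
# normal approximation with continuity correction is used
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class DifferentialCall:
    feature_id: str
    x: int
    p_ga: float
    p_wilcoxon: float
    direction: int
    passes: bool


def binomial_selection_pvalue(x: int, n: int, m: int, v: int) -> float:
    """Upper-tail binomial probability of >= x selections in n runs.

    ``m/v`` is the null per-run selection probability.  Uses the survival
    function, which is exact at both boundaries (P = 1 at x = 0; a single
    term at x = n).
    """
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if not 1 <= m <= v:
        raise ValueError("m must lie in [1, v]")
    return float(stats.binom.sf(x - 1, n, m / v))


def _exact_rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum P by enumerating all group assignments (midranks)."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    center = n1 * (n1 + n2 + 1) / 2.0
    observed = abs(ranks[:n1].sum() - center)
    total = comb(n1 + n2, n1)
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        if abs(ranks[list(idx)].sum() - center) >= observed - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(values_class1, values_class0) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P with midrank ties.

    For combined sizes <= 12 the P value is the exact permutation
    probability; larger samples use the tie-corrected normal approximation
    with continuity correction.
    """
    a = np.asarray(values_class1, dtype=float)
    b = np.asarray(values_class0, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.size + b.size <= EXACT_ENUMERATION_LIMIT:
        return _exact_rank_sum_pvalue(a, b)
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def call_differentials(
    counts: SelectionCounts,
    X,
    y,
    feature_ids=None,
    alpha_ga: float = 0.001,
    alpha_wx: float = 0.05,
) -> pd.DataFrame:
    """Apply the dual criterion to every feature.

    Returns a DataFrame with columns ``feature_id, x, n, p_ga, p_wilcoxon,
    direction, passes``; ``direction`` is the sign of
    (median class 1 - median class 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[1] != counts.v:
        raise ValueError("selection counts and X must share feature indexing")
    ids = feature_ids if feature_ids is not None else [
        str(j) for j in range(counts.v)
    ]
    rows = []
    for j in range(counts.v):
        x = int(counts.counts[j])
        p_ga = binomial_selection_pvalue(x, counts.n, counts.m, counts.v)
        p_wx = wilcoxon_rank_sum(X[y == 1, j], X[y == 0, j])
        diff = float(np.median(X[y == 1, j]) - np.median(X[y == 0, j]))
        direction = int(np.sign(diff))
        rows.append(
            DifferentialCall(
                feature_id=str(ids[j]), x=x, p_ga=p_ga, p_wilcoxon=p_wx,
                direction=direction,
                passes=bool(p_ga < alpha_ga and p_wx < alpha_wx),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.insert(2, "n", counts.n)
    return out
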