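"""Independent reference implementations used as correctness oracles.

Each function here is deliberately written from first principles, without
reusing any package internals, so agreement with the package is meaningful
evidence of correctness rather than a tautology.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


def primal_opls(X, y, ao):
    """X-space (primal) OPLS fit; returns a prediction closure.

    Follows the classical NIPALS orthogonal-projection recipe: a single
    predictive weight vector from the X'y covariance, ``ao`` Y-orthogonal
    components peeled off by deflating X, and a univariate regression of the
    response on the final predictive score.
    """
    Xm, ym = X.mean(0), y.mean()
    Xc, yc = X - Xm, y - ym
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    Wo, Po = [], []
    Xi = Xc.copy()
    for _ in range(ao):
        t = Xi @ w
        p = Xi.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            break
        wo /= norm
        to = Xi @ wo
        po = Xi.T @ to / (to @ to)
        Xi = Xi - np.outer(to, po)
        Wo.append(wo)
        Po.append(po)
    t = Xi @ w
    b = (t @ yc) / (t @ t)

    def predict(Xn):
        Xnc = Xn - Xm
        for wo, po in zip(Wo, Po):
            Xnc = Xnc - np.outer(Xnc @ wo, po)
        return (Xnc @ w) * b + ym

    return predict


def exact_binomial_tail(x, n, m, v):
    """Brute-force rational-arithmetic upper-tail binomial probability."""
    p = Fraction(m, v)
    return float(
        sum(comb(n, i) * p ** i * (1 - p) ** (n - i) for i in range(x, n + 1))
    )


def rank_sum_enumeration(a, b):
    """Two-sided rank-sum P value by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    center = n1 * (len(pooled) + 1) / 2.0
    obs = abs(sum(ranks[:n1]) - center)
    hits = sum(
        1 for idx in combinations(range(len(pooled)), n1)
        if abs(sum(ranks[i] for i in idx) - center) >= obs - 1e-9
    )
    return hits / comb(len(pooled), n1)
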