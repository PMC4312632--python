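"""Synthetic minority oversampling (SMOTE) and its neighbor-parameter search.

Each synthetic point is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``,
``x`` a minority sample and ``x_nn`` one of its ``n_neighbors`` nearest
minority neighbors (Euclidean), so synthetic points never leave the convex
hull of the minority class and the original samples are never mutated.

The neighbor parameter is tuned by the wrapper procedure: for each candidate
``n``, split the cohort 50/50 (stratified), SMOTE-balance the training half,
run a GA-K-OPLS selection, and score the balanced prediction error of the
best mask on the designated test set — by default the original full cohort
(the protocol this reproduces scores on data that overlaps the training
half; a strict held-out mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "smote_oversample", "rebalance", "optimize_smote_n"]


@dataclass
class SmoteConfig:
    """SMOTE settings: neighbor count, target minority:majority ratio, seed."""

    n_neighbors: int = 3
    target_ratio: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be at least 1")
        if not 0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")


def smote_oversample(X_minority, n_synthetic: int, n_neighbors: int, rng,
                     return_parents: bool = False):
    """Generate ``n_synthetic`` points interpolated within the minority class.

    Returns the synthetic array, or ``(synthetic, parent_idx, neighbor_idx,
    u)`` when ``return_parents`` is true (used by the geometry checks).
    """
    X_minority = np.asarray(X_minority, dtype=float)
    n_min = X_minority.shape[0]
    if n_min <= n_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed n_neighbors {n_neighbors}"
        )
    rng = np.random.default_rng(rng)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X_minority)
    # first neighbor is the point itself
    neigh_idx = nn.kneighbors(X_minority, return_distance=False)[:, 1:]
    parents = rng.integers(0, n_min, size=n_synthetic)
    choice = rng.integers(0, n_neighbors, size=n_synthetic)
    neighbors = neigh_idx[parents, choice]
    u = rng.random(n_synthetic)
    synthetic = (
        X_minority[parents]
        + u[:, None] * (X_minority[neighbors] - X_minority[parents])
    )
    if return_parents:
        return synthetic, parents, neighbors, u
    return synthetic


def rebalance(X, y, config: SmoteConfig, rng=None):
    """Append SMOTE points so that minority:majority = ``target_ratio``.

    Original samples come first and are untouched.  Returns ``(X_aug, y_aug)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    target = int(round(config.target_ratio * n0))
    n_synth = max(target - n1, 0)
    if n_synth == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    synth = smote_oversample(X[y == 1], n_synth, config.n_neighbors, rng)
    return np.vstack([X, synth]), np.concatenate([y, np.ones(n_synth, dtype=int)])


def optimize_smote_n(
    X,
    y,
    n_grid,
    ga_config,
    kopls_config,
    n_repeats: int = 10,
    seed: int = 0,
    target_ratio: float = 1.0,
    strict_holdout: bool = False,
):
    """Pick the SMOTE neighbor parameter by repeated GA-K-OPLS evaluation.

    For every candidate ``n``: ``n_repeats`` times, draw a stratified 50%
    training split, SMOTE-balance it with ``n`` neighbors, run one GA with
    the balanced-error fitness, and record the best fitness.  The winning
    ``n`` minimizes the mean error; ties go to the smaller ``n``.

    Returns ``(best_n, table)`` where ``table`` has columns
    ``n, mean_error, sd_error``.
    """
    from .ga import make_split_fitness, run_ga  # deferred: circular import

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n_grid = sorted(int(n) for n in n_grid)
    if not n_grid:
        raise ValueError("n_grid must be nonempty")
    n1 = int(y.sum())
    if max(n_grid) >= n1 // 2:
        raise ValueError(
            "every candidate n must be smaller than the minority count in a half split"
        )
    ss = np.random.SeedSequence(seed)
    rows = []
    for n in n_grid:
        errors = []
        for child in ss.spawn(n_repeats):
            rng = np.random.default_rng(child)
            split_seed = int(rng.integers(2 ** 31))
            tr, te = train_test_split(
                np.arange(y.size), test_size=0.5, stratify=y, random_state=split_seed
            )
            smote_cfg = SmoteConfig(n_neighbors=n, target_ratio=target_ratio)
            fitness = make_split_fitness(
                X, y, tr, te, smote_cfg, kopls_config, rng,
                strict_holdout=strict_holdout,
            )
            result = run_ga(X.shape[1], fitness, ga_config, rng)
            errors.append(result.best_fitness)
        rows.append((n, float(np.mean(errors)), float(np.std(errors, ddof=1)) if
                     len(errors) > 1 else 0.0))
    table = pd.DataFrame(rows, columns=["n", "mean_error", "sd_error"])
    best_n = int(table.loc[table["mean_error"].idxmin(), "n"])
    return best_n, table
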