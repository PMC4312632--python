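"""Genetic-algorithm wrapper feature selection with K-OPLS balanced-error fitness.

Chromosomes are binary masks over the feature set.  The fitness of a mask is
the balanced prediction error (1 - mean of sensitivity and specificity) of a
K-OPLS classifier trained on the SMOTE-balanced training split restricted to
the masked features, scored on a designated test set.  The GA is the
canonical simple GA: fitness-proportional selection, single-point crossover,
bitwise mutation, elitism of one.  Repeated independent runs produce
per-feature selection tallies consumed by the selection-frequency test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .kopls import (
    KoplsConfig,
    center_kernel_test,
    center_kernel_train,
    fit_kopls,
    gaussian_kernel,
    predict_kopls,
    resolve_sigma,
)
from .metrics import balanced_error
from .smote import SmoteConfig, rebalance

__all__ = [
    "GAConfig",
    "GARunResult",
    "SelectionCounts",
    "evaluate_fitness",
    "make_split_fitness",
    "run_ga",
    "repeat_runs",
]


@dataclass
class GAConfig:
    """Simple-GA hyperparameters.

    Defaults follow the study protocol: population 30, 150 generations,
    initial per-gene selection probability 0.1, crossover probability 0.7,
    and 50 independent runs for the selection tallies.  Mutation probability
    and elitism are canonical simple-GA choices.
    """

    population_size: int = 30
    n_generations: int = 150
    init_selection_ratio: float = 0.1
    crossover_prob: float = 0.7
    mutation_prob: float = 0.01
    n_runs: int = 50
    elitism: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for name in ("init_selection_ratio", "crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


@dataclass
class GARunResult:
    """Best chromosome of one GA run with its per-generation fitness trace."""

    best_mask: np.ndarray
    best_fitness: float
    fitness_trace: list = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return int(self.best_mask.sum())


@dataclass
class SelectionCounts:
    """Per-feature selection tallies over repeated GA runs.

    ``counts[j]`` is the number of runs whose best mask includes feature j;
    ``n`` the number of runs, ``v`` the number of features, ``m`` the mean
    number of features selected per run rounded to an integer.
    """

    counts: np.ndarray
    n: int
    v: int
    m: int
    run_masks: np.ndarray = None  # (n_runs, v) bool, optional

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.v,):
            raise ValueError("counts must have one entry per feature")
        if self.counts.min() < 0 or self.counts.max() > self.n:
            raise ValueError("counts must lie in [0, n]")
        if not 1 <= self.m <= self.v:
            raise ValueError("m must lie in [1, v]")

    def to_frame(self, feature_ids=None) -> pd.DataFrame:
        ids = feature_ids if feature_ids is not None else [
            str(j) for j in range(self.v)
        ]
        return pd.DataFrame({"feature_id": ids, "x": self.counts, "n": self.n})


def evaluate_fitness(mask, X_train, y_train, X_test, y_test,
                     kopls_config: KoplsConfig) -> float:
    """Balanced prediction error of K-OPLS restricted to the masked features.

    An empty mask (or any degenerate fit) scores the worst possible error
    1.0 rather than raising, so the GA tolerates pathological chromosomes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 1.0
    Xtr = X_train[:, mask]
    Xte = X_test[:, mask]
    try:
        sigma = resolve_sigma(kopls_config.sigma, Xtr)
        Kc, stats = center_kernel_train(gaussian_kernel(Xtr, Xtr, sigma))
        state = fit_kopls(Kc, y_train, kopls_config.ao)
        Kte = center_kernel_test(gaussian_kernel(Xte, Xtr, sigma), stats)
        pred = (predict_kopls(state, Kte) >= 0.5).astype(int)
        return balanced_error(y_test, pred)
    except (ValueError, np.linalg.LinAlgError):
        return 1.0


def make_split_fitness(X, y, train_idx, test_idx, smote_config: SmoteConfig,
                       kopls_config: KoplsConfig, rng, strict_holdout: bool = False):
    """Build a cached mask -> balanced-error closure for one data split.

    The training half is SMOTE-balanced once (not per generation).  The test
    set is the full original cohort by default, reproducing the protocol
    this package implements; with ``strict_holdout`` only the held-out half
    is scored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    Xtr_aug, ytr_aug = rebalance(X[train_idx], y[train_idx], smote_config, rng=rng)
    if strict_holdout:
        X_test, y_test = X[test_idx], y[test_idx]
    else:
        X_test, y_test = X, y
    cache: dict = {}

    def fitness(mask) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(
                mask, Xtr_aug, ytr_aug, X_test, y_test, kopls_config
            )
        return cache[key]

    return fitness


def run_ga(n_features: int, fitness, config: GAConfig, rng) -> GARunResult:
    """Evolve binary masks for ``config.n_generations`` generations.

    ``fitness`` maps a boolean mask to an error in [0, 1] (minimized).
    Selection is fitness-proportional on ``1 - error``; deterministic given
    the supplied generator.  The fitness trace records the population best
    after the initial evaluation and after every generation, so with elitism
    it is non-increasing.
    """
    if n_features < 2:
        raise ValueError("need at least two features")
    rng = np.random.default_rng(rng)
    pop = rng.random((config.population_size, n_features)) < config.init_selection_ratio
    errors = np.array([fitness(ind) for ind in pop])
    trace = [float(errors.min())]

    for _ in range(config.n_generations):
        order = np.argsort(errors, kind="stable")
        elite = pop[order[: config.elitism]].copy()
        weights = 1.0 - errors
        total = weights.sum()
        p = np.full(errors.size, 1.0 / errors.size) if total <= 0 else weights / total

        children = []
        need = config.population_size - config.elitism
        while len(children) < need:
            i, j = rng.choice(errors.size, size=2, p=p)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < config.crossover_prob and n_features > 1:
                point = rng.integers(1, n_features)
                a[point:], b[point:] = pop[j][point:], pop[i][point:]
            children.append(a)
            if len(children) < need:
                children.append(b)
        children = np.array(children)
        flips = rng.random(children.shape) < config.mutation_prob
        children ^= flips
        pop = np.vstack([elite, children]) if config.elitism else children
        errors = np.array([fitness(ind) for ind in pop])
        trace.append(float(errors.min()))

    best = int(np.argmin(errors))
    return GARunResult(
        best_mask=pop[best].copy(), best_fitness=float(errors[best]),
        fitness_trace=trace,
    )


def repeat_runs(
    X,
    y,
    ga_config: GAConfig,
    smote_config: SmoteConfig,
    kopls_config: KoplsConfig,
    seed: int = 0,
    strict_holdout: bool = False,
    fixed_split: bool = False,
) -> SelectionCounts:
    """Run ``ga_config.n_runs`` independent GAs and tally feature selections.

    Each run draws a fresh stratified 50% training split and SMOTE-balances
    it (``fixed_split`` reuses the first split across runs).  Counts feed the
    binomial selection-frequency test.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    v = X.shape[1]
    ss = np.random.SeedSequence(seed)
    counts = np.zeros(v, dtype=int)
    masks, popcounts = [], []
    first_split = None
    for child in ss.spawn(ga_config.n_runs):
        rng = np.random.default_rng(child)
        if fixed_split and first_split is not None:
            tr, te = first_split
        else:
            split_seed = int(rng.integers(2 ** 31))
            tr, te = train_test_split(
                np.arange(y.size), test_size=0.5, stratify=y, random_state=split_seed
            )
            if first_split is None:
                first_split = (tr, te)
        fitness = make_split_fitness(
            X, y, tr, te, smote_config, kopls_config, rng,
            strict_holdout=strict_holdout,
        )
        result = run_ga(v, fitness, ga_config, rng)
        counts += result.best_mask.astype(int)
        masks.append(result.best_mask)
        popcounts.append(result.n_selected)
    m = int(round(float(np.mean(popcounts))))
    m = min(max(m, 1), v)
    return SelectionCounts(
        counts=counts, n=ga_config.n_runs, v=v, m=m, run_masks=np.array(masks)
    )
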