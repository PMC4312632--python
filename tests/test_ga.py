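import numpy as np
import pytest

from metabostrat import GAConfig, KoplsConfig, SmoteConfig, repeat_runs, run_ga
from metabostrat.ga import SelectionCounts, evaluate_fitness


def popcount_fitness(mask):
    """Parsimony toy: smaller masks are fitter (analytic sanity oracle)."""
    return mask.sum() / mask.size


class TestRunGA:
    def test_popcount_toy_collapses_masks(self):
        cfg = GAConfig(population_size=20, n_generations=40,
                       init_selection_ratio=0.5)
        res = run_ga(50, popcount_fitness, cfg, np.random.default_rng(0))
        assert res.n_selected < 0.5 * 50 * 0.5  # well below the initial mean

    def test_same_seed_identical_results(self):
        cfg = GAConfig(population_size=10, n_generations=10)
        a = run_ga(20, popcount_fitness, cfg, np.random.default_rng(42))
        b = run_ga(20, popcount_fitness, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(a.best_mask, b.best_mask)
        assert a.fitness_trace == b.fitness_trace

    def test_elitism_makes_trace_nonincreasing(self):
        cfg = GAConfig(population_size=12, n_generations=30, mutation_prob=0.05)
        res = run_ga(30, popcount_fitness, cfg, np.random.default_rng(1))
        trace = res.fitness_trace
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        assert res.best_fitness == min(trace)

    def test_runs_exactly_k_generations(self):
        cfg = GAConfig(population_size=8, n_generations=7)
        res = run_ga(10, popcount_fitness, cfg, np.random.default_rng(2))
        assert len(res.fitness_trace) == 8  # initial population + 7 generations


class TestEvaluateFitness:
    @staticmethod
    def _separable(seed=0, n=40, p=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        X[y == 1, 0] += 6.0  # only feature 0 carries signal
        return X, y

    def test_empty_mask_scores_worst_without_raising(self):
        X, y = self._separable()
        err = evaluate_fitness(np.zeros(6, bool), X, y, X, y,
                               KoplsConfig(sigma="median", ao=0))
        assert err == 1.0

    def test_perfect_classifier_scores_zero(self):
        X, y = self._separable()
        mask = np.zeros(6, bool)
        mask[0] = True
        err = evaluate_fitness(mask, X, y, X, y, KoplsConfig(sigma="median", ao=0))
        assert err == 0.0

    def test_informative_mask_beats_noise_mask(self):
        wins = 0
        for seed in range(10):
            X, y = self._separable(seed)
            good = np.zeros(6, bool)
            good[0] = True
            bad = np.zeros(6, bool)
            bad[3] = True
            cfg = KoplsConfig(sigma="median", ao=0)
            wins += evaluate_fitness(good, X, y, X, y, cfg) < evaluate_fitness(
                bad, X, y, X, y, cfg
            )
        assert wins >= 9

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(3)
        errs = []
        for seed in range(10):
            X, y = self._separable(seed, n=60)
            yp = rng.permutation(y)
            mask = np.ones(6, bool)
            errs.append(evaluate_fitness(mask, X, yp, X, yp,
                                         KoplsConfig(sigma="median", ao=0)))
        # overlapping train/test keeps this slightly optimistic; it must not
        # approach the perfect-classification regime
        assert 0.15 < np.mean(errs) <= 0.55


class TestRepeatRuns:
    @staticmethod
    def _counts(n_runs=3, seed=0):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 8))
        y = np.r_[np.zeros(40), np.ones(20)].astype(int)
        X[y == 1, 1] += 4.0
        cfg = GAConfig(population_size=8, n_generations=4, n_runs=n_runs)
        return repeat_runs(X, y, cfg, SmoteConfig(n_neighbors=2),
                           KoplsConfig(sigma="median", ao=0), seed=seed)

    def test_single_run_counts_equal_best_mask(self):
        counts = self._counts(n_runs=1)
        np.testing.assert_array_equal(counts.counts,
                                      counts.run_masks[0].astype(int))

    def test_counting_identity(self):
        counts = self._counts(n_runs=4)
        assert counts.counts.sum() == counts.run_masks.sum()

    def test_m_is_rounded_mean_popcount(self):
        counts = self._counts(n_runs=4)
        assert counts.m == int(round(counts.run_masks.sum(1).mean()))

    def test_deterministic_given_seed(self):
        a = self._counts(seed=5)
        b = self._counts(seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestNullExchangeability:
    def test_counts_show_no_feature_index_bias_on_null_data(self):
        """On a label-free (null) cohort no feature is special, so selection
        counts must be exchangeable across features: no trend in the feature
        index, and the same count distribution after permuting columns."""
        from scipy import stats

        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 12))
        y = np.r_[np.zeros(35), np.ones(15)].astype(int)
        cfg = GAConfig(population_size=10, n_generations=5, n_runs=25)
        kcfg = KoplsConfig(sigma="median", ao=0)
        counts = repeat_runs(X, y, cfg, SmoteConfig(n_neighbors=2), kcfg,
                             seed=0).counts
        rho, p_trend = stats.spearmanr(np.arange(counts.size), counts)
        assert p_trend > 0.01

        perm = rng.permutation(12)
        counts_p = repeat_runs(X[:, perm], y, cfg, SmoteConfig(n_neighbors=2),
                               kcfg, seed=0).counts
        p_same = stats.mannwhitneyu(counts, counts_p).pvalue
        assert p_same > 0.01


class TestSelectionCounts:
    def test_counts_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SelectionCounts(counts=np.array([5, 1]), n=4, v=2, m=1)

    def test_frame_has_feature_ids(self):
        sc = SelectionCounts(counts=np.array([2, 0, 1]), n=3, v=3, m=1)
        df = sc.to_frame(["a", "b", "c"])
        assert df.feature_id.tolist() == ["a", "b", "c"]
        assert (df.n == 3).all()


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(population_size=1)
    with pytest.raises(ValueError):
        GAConfig(crossover_prob=1.5)
    with pytest.raises(ValueError):
        GAConfig(elitism=30, population_size=30)
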