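import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabostrat import KOPLS, KoplsConfig, grid_search_accv
from oracles import primal_opls

from metabostrat.kopls import (
    KOPLSResults,
    center_kernel_test,
    center_kernel_train,
    fit_kopls,
    fit_statistics,
    gaussian_kernel,
    median_pairwise_distance,
    predict_kopls,
)


class TestGaussianKernel:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        K = gaussian_kernel(X, X, 1.3)
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)

    def test_wide_kernel_saturates_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))
        K = gaussian_kernel(X, X, 1e6)
        np.testing.assert_allclose(K, 1.0, atol=1e-9)

    def test_matches_pairwise_hand_computation(self):
        X1 = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, -1.0]])
        X2 = np.array([[1.0, 1.0], [-2.0, 0.5]])
        sigma = 0.9
        expected = np.empty((3, 2))
        for i in range(3):
            for j in range(2):
                d2 = np.sum((X1[i] - X2[j]) ** 2)
                expected[i, j] = np.exp(-d2 / (2 * sigma ** 2))
        np.testing.assert_allclose(gaussian_kernel(X1, X2, sigma), expected,
                                   atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 4))
        K = gaussian_kernel(X, X, float(rng.uniform(0.3, 3.0)))
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.eye(2), np.eye(2), 0.0)


class TestKernelCentering:
    def test_row_and_column_means_vanish(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(10, 5))
        Kc, _ = center_kernel_train(A @ A.T)
        assert np.abs(Kc.mean(0)).max() < 1e-10
        assert np.abs(Kc.mean(1)).max() < 1e-10

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(8, 3))
        Kc, _ = center_kernel_train(A @ A.T)
        Kcc, _ = center_kernel_train(Kc)
        np.testing.assert_allclose(Kcc, Kc, atol=1e-12)

    def test_rank_one_ones_kernel_centers_to_zero(self):
        K = np.ones((6, 6))
        Kc, _ = center_kernel_train(K)
        np.testing.assert_allclose(Kc, 0.0, atol=1e-12)

    def test_test_centering_consistent_with_train(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 4))
        K = gaussian_kernel(X, X, 1.0)
        Kc, stats = center_kernel_train(K)
        np.testing.assert_allclose(center_kernel_test(K, stats), Kc, atol=1e-12)
        # a single test point equal to training point j reproduces row j
        np.testing.assert_allclose(
            center_kernel_test(K[[3], :], stats)[0], Kc[3], atol=1e-12
        )

    def test_linear_kernel_matches_feature_space_centering(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(7, 3))
        Xt = rng.normal(size=(4, 3))
        _, stats = center_kernel_train(X @ X.T)
        got = center_kernel_test(Xt @ X.T, stats)
        Xc = X - X.mean(0)
        expected = (Xt - X.mean(0)) @ Xc.T
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_nonsquare_train_kernel_rejected(self):
        with pytest.raises(ValueError):
            center_kernel_train(np.ones((3, 4)))


class TestFitPredict:
    def test_separable_clusters_classified_perfectly(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(5, 0.2, (15, 2))])
        y = np.r_[np.zeros(15), np.ones(15)]
        res = KOPLS(X, y, n_ortho=0, kernel="linear").fit()
        assert (res.predict_class(X) == y).all()

    @pytest.mark.parametrize("ao", [0, 1, 2, 3])
    def test_linear_kernel_equals_primal_opls(self, ao):
        rng = np.random.default_rng(ao + 10)
        X = rng.normal(size=(25, 8))
        y = (rng.random(25) < 0.4).astype(float)
        Xt = rng.normal(size=(6, 8))
        res = KOPLS(X, y, n_ortho=ao, kernel="linear").fit()
        oracle = primal_opls(X, y, ao)
        np.testing.assert_allclose(res.predict(Xt), oracle(Xt), atol=1e-8)

    def test_training_prediction_reproduces_fitted_values(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 5))
        y = (rng.random(20) < 0.5).astype(float)
        y[:2] = [0, 1]
        res = KOPLS(X, y, sigma="median", n_ortho=2).fit()
        np.testing.assert_allclose(res.predict(X), res.fittedvalues, atol=1e-10)

    def test_duplicated_test_row_duplicated_prediction(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 4))
        y = np.r_[np.zeros(8), np.ones(7)]
        res = KOPLS(X, y, sigma=1.0, n_ortho=1).fit()
        pred = res.predict(np.vstack([X[2], X[2]]))
        assert pred[0] == pytest.approx(pred[1], abs=1e-12)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 6))
        y = (rng.random(30) < 0.3).astype(float)
        y[:2] = [0, 1]
        res = KOPLS(X, y, sigma="median", n_ortho=3).fit()
        To = res.scores_orthogonal
        tp = res.scores_predictive
        scale = np.linalg.norm(tp) * np.linalg.norm(To, axis=0)
        assert np.abs(To.T @ tp / scale).max() < 1e-8

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_kopls(np.eye(4) - 0.25, np.ones(4), 0)

    def test_too_many_orthogonal_components_rejected(self):
        with pytest.raises(ValueError):
            fit_kopls(np.eye(4), np.array([0, 0, 1, 1.0]), 4)

    def test_adding_orthogonal_component_never_decreases_r2y(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 10))
        y = (rng.random(40) < 0.5).astype(float)
        y[:2] = [0, 1]
        r2 = [KOPLS(X, y, sigma=2.0, n_ortho=ao).fit().r2y for ao in range(4)]
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_round_trip_serialization(self, tmp_path):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(18, 4))
        y = np.r_[np.zeros(9), np.ones(9)]
        res = KOPLS(X, y, sigma="median", n_ortho=2).fit()
        path = tmp_path / "model.json"
        res.save(path)
        back = KOPLSResults.load(path)
        Xt = rng.normal(size=(5, 4))
        np.testing.assert_allclose(back.predict(Xt), res.predict(Xt), atol=1e-12)


class TestFitStatistics:
    def test_mean_predictor_gives_nonpositive_q2(self):
        # pure-noise predictors cannot beat the mean under CV
        rng = np.random.default_rng(17)
        X = rng.normal(size=(40, 5))
        y = np.r_[np.zeros(20), np.ones(20)]
        _, _, q2 = fit_statistics(X, y, KoplsConfig(sigma=50.0, ao=0, n_folds=5))
        assert q2 <= 0.05

    def test_q2_matches_manual_fold_loop(self):
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(18)
        X = rng.normal(size=(20, 4))
        y = np.r_[np.zeros(10), np.ones(10)]
        X[y == 1] += 1.0
        cfg = KoplsConfig(sigma=2.0, ao=1, n_folds=5)
        _, _, q2 = fit_statistics(X, y, cfg, seed=3)
        press = 0.0
        skf = StratifiedKFold(5, shuffle=True, random_state=3)
        for tr, te in skf.split(X, y):
            Kc, stats = center_kernel_train(gaussian_kernel(X[tr], X[tr], 2.0))
            st = fit_kopls(Kc, y[tr], 1)
            Kte = center_kernel_test(gaussian_kernel(X[te], X[tr], 2.0), stats)
            press += np.sum((y[te] - predict_kopls(st, Kte)) ** 2)
        expected = 1 - press / np.sum((y - y.mean()) ** 2)
        assert q2 == pytest.approx(expected, rel=1e-10)

    def test_near_perfect_fit_r2y_approaches_one(self):
        # narrow kernel on well-separated data interpolates the response
        rng = np.random.default_rng(19)
        X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(4, 0.3, (10, 2))])
        y = np.r_[np.zeros(10), np.ones(10)]
        res = KOPLS(X, y, sigma=0.3, n_ortho=2).fit()
        assert res.r2y > 0.99

    def test_r2_fractions_in_unit_interval(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(30, 5))
        y = (rng.random(30) < 0.4).astype(float)
        y[:2] = [0, 1]
        res = KOPLS(X, y, sigma="median", n_ortho=2).fit()
        assert 0.0 <= res.r2x <= 1.0
        assert 0.0 <= res.r2y <= 1.0


class TestGridSearch:
    def test_separable_data_reaches_perfect_accv(self, separable=None):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(6, 0.3, (20, 2))])
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        surface, sigma, ao = grid_search_accv(X, y, [1.0, 2.0], [0, 1],
                                              n_folds=5, seed=0)
        assert surface.values.max() == 1.0
        assert ((surface.values >= 0) & (surface.values <= 1)).all()
        assert ao == 0  # tie broken toward fewer components

    def test_permuted_labels_near_majority_rate(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(60, 5))
        y = np.r_[np.zeros(40), np.ones(20)].astype(int)
        y = rng.permutation(y)
        surface, _, _ = grid_search_accv(X, y, [1.0, 2.0], [0, 1], n_folds=5, seed=0)
        # binomial noise around the 2/3 majority rate
        assert surface.values.max() < 40 / 60 + 3 * np.sqrt(40 * 20 / 60 ** 3) + 0.05

    def test_reordering_invariance_given_same_folds(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(30, 4))
        y = np.r_[np.zeros(18), np.ones(12)].astype(int)
        X[y == 1] += 1.5
        s1, _, _ = grid_search_accv(X, y, [1.0], [0, 1], n_folds=3, seed=9)
        perm = rng.permutation(30)
        s2, _, _ = grid_search_accv(X[perm], y[perm], [1.0], [0, 1], n_folds=3,
                                    seed=9)
        # pooled CV accuracy depends only on the fold partition, which is
        # stratified and seeded; allow the partition to differ slightly
        assert np.abs(s1.values - s2.values).max() <= 3 / 30

    def test_insufficient_minority_for_folds_suggests_fewer(self):
        X = np.random.default_rng(1).normal(size=(12, 3))
        y = np.r_[np.zeros(9), np.ones(3)].astype(int)
        with pytest.raises(ValueError, match="fewer folds"):
            grid_search_accv(X, y, [1.0], [0], n_folds=5)


def test_median_distance_deterministic_and_positive():
    rng = np.random.default_rng(24)
    X = rng.normal(size=(300, 5))
    d1 = median_pairwise_distance(X)
    d2 = median_pairwise_distance(X)
    assert d1 == d2 > 0
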