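import numpy as np
import pytest

import glycospec as gs
from glycospec.regression import (
    PredictionSet,
    evaluate_split,
    loocv,
    pls_fit,
    pls_predict,
    r_squared,
    rmse,
    rpd,
    select_lv,
    split_70_30,
    svr_fit,
    svr_predict,
    tune_svr,
)


class TestMetrics:
    def test_perfect_predictions(self):
        p = PredictionSet([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r_squared(p) == pytest.approx(1.0)
        assert rmse(p) == pytest.approx(0.0)

    def test_mean_predictor_scores_zero(self):
        p = PredictionSet([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert r_squared(p) == pytest.approx(0.0)

    def test_hand_computed_r2(self):
        assert r_squared(PredictionSet([1, 2, 3], [1, 2, 4])) == pytest.approx(0.5)

    def test_hand_computed_rmse(self):
        # residuals 3 and -4 -> sqrt(25/2)
        assert rmse(PredictionSet([3.0, 0.0], [0.0, 4.0])) == pytest.approx(3.5355, abs=1e-4)

    def test_constant_residual_rmse(self):
        assert rmse(PredictionSet([5.0, 6.0], [2.0, 3.0])) == pytest.approx(3.0)

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError):
            r_squared(PredictionSet([2.0, 2.0], [1.0, 3.0]))

    def test_rpd_identity_and_scaling(self):
        assert rpd(50.0, 50.0) == pytest.approx(1.0)
        assert rpd(100.0, 50.0) == pytest.approx(2 * rpd(50.0, 50.0))

    def test_rpd_published_pair(self):
        # SD back-solved from printed RMSEp 54.12 / RPD 1.81
        assert rpd(97.96, 54.12) == pytest.approx(1.81, abs=0.005)

    def test_rpd_zero_rmse_rejected(self):
        with pytest.raises(ValueError):
            rpd(10.0, 0.0)


class TestPLS:
    def test_univariate_proportional_response(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        model = pls_fit(x, 2 * x.ravel(), 1)
        assert model.coef[0] == pytest.approx(2.0)
        assert r_squared(PredictionSet(2 * x.ravel(), pls_predict(model, x))) == pytest.approx(1.0)

    def test_matches_ols_at_full_rank(self, rng):
        X = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        model = pls_fit(X, y, 8)
        Xc = X - X.mean(0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(pls_predict(model, X), Xc @ beta + y.mean(), atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        T = pls_fit(X, y, 6).scores
        Tn = T / np.linalg.norm(T, axis=0)
        off = Tn.T @ Tn - np.eye(6)
        assert np.abs(off).max() < 1e-8

    def test_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        ours = pls_predict(pls_fit(X, y, 5), X)
        ref = PLSRegression(n_components=5, scale=False).fit(X, y).predict(X).ravel()
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_recovers_generator_coefficients_on_noiseless_data(self, rng):
        # noiseless linear map: collapsed coefficients reproduce the truth
        p, n = 12, 60
        beta_true = rng.standard_normal(p)
        X = rng.standard_normal((n, p))
        y = X @ beta_true
        model = pls_fit(X, y, p)
        np.testing.assert_allclose(model.coef, beta_true, rtol=1e-6)

    @pytest.mark.parametrize("n_lv", [0, 100])
    def test_bad_lv_rejected(self, rng, n_lv):
        with pytest.raises(ValueError):
            pls_fit(rng.random((10, 5)), rng.random(10), n_lv)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError):
            pls_fit(rng.random((10, 5)), np.ones(10), 2)


class TestSelectLV:
    def test_noiseless_low_rank_needs_few_lvs(self, rng):
        n, p, r = 60, 20, 3
        T = rng.standard_normal((n, r))
        P = rng.standard_normal((r, p))
        X = T @ P
        y = T @ np.array([1.0, -2.0, 0.5])
        n_lv = select_lv(X, y, max_lv=10, rng=np.random.default_rng(1))
        assert n_lv <= r
        from glycospec._pls import cv_rmse_path, kfold_indices

        folds = kfold_indices(n, 5, np.random.default_rng(1))
        assert cv_rmse_path(X, y, 10, folds)[n_lv - 1] < 1e-6 * np.std(y)

    def test_max_lv_one(self, rng):
        assert select_lv(rng.random((20, 5)), rng.random(20), max_lv=1) == 1

    def test_returned_lv_minimizes_path(self, rng):
        from glycospec._pls import cv_rmse_path, kfold_indices

        X = rng.standard_normal((40, 10))
        y = X[:, 0] + 0.5 * rng.standard_normal(40)
        lv_rng = np.random.default_rng(3)
        n_lv = select_lv(X, y, max_lv=8, rng=lv_rng)
        folds = kfold_indices(40, 5, np.random.default_rng(3))
        path = cv_rmse_path(X, y, 8, folds)
        assert path[n_lv - 1] == path.min()


class TestSVR:
    def test_constant_tube(self, rng):
        X = rng.random((20, 3))
        y = 10.0 + 0.05 * rng.standard_normal(20)
        model = svr_fit(X, y, C=10.0, epsilon=1.0)
        assert np.abs(svr_predict(model, X) - 10.0).max() < 1.0

    def test_fits_smooth_nonlinearity(self):
        x = np.linspace(0, 2 * np.pi, 120)[:, None]
        y = np.sin(x).ravel()
        model = svr_fit(x, y, C=100.0, epsilon=0.01)
        assert rmse(PredictionSet(y, svr_predict(model, x))) < 0.1

    def test_feature_scale_invariant(self, rng):
        X = rng.random((30, 4))
        y = rng.random(30)
        a = svr_predict(svr_fit(X, y, C=10, epsilon=0.1), X)
        b = svr_predict(svr_fit(X * 1000, y, C=10, epsilon=0.1), X * 1000)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_invalid_hyperparameters_rejected(self, rng):
        with pytest.raises(ValueError):
            svr_fit(rng.random((10, 2)), rng.random(10), C=-1.0)
        with pytest.raises(ValueError):
            svr_fit(rng.random((10, 2)), rng.random(10), epsilon=-0.5)

    def test_tune_single_cell_grid(self, rng):
        X = rng.random((20, 3))
        y = rng.random(20)
        assert tune_svr(X, y, C_grid=[7.0], eps_grid=[0.3]) == (7.0, 0.3)

    def test_tuned_pair_minimizes_grid(self, rng):
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + 0.1 * rng.standard_normal(40)
        C_grid, eps_grid = (1.0, 100.0), (0.05, 1.0)
        C, eps = tune_svr(X, y, C_grid, eps_grid, rng=np.random.default_rng(2))
        from glycospec._pls import kfold_indices

        folds = kfold_indices(40, 5, np.random.default_rng(2))

        def score(Cv, ev):
            sse = 0.0
            for test in folds:
                train = np.setdiff1d(np.arange(40), test)
                m = svr_fit(X[train], y[train], C=Cv, epsilon=ev)
                r = y[test] - svr_predict(m, X[test])
                sse += r @ r
            return np.sqrt(sse / 40)

        best = score(C, eps)
        for Cv in C_grid:
            for ev in eps_grid:
                assert best <= score(Cv, ev) + 1e-9


class TestLOOCV:
    def test_mean_only_estimator_hand_folds(self):
        # y = [0, 0, 3]: leaving each out predicts the mean of the rest
        class MeanModel:
            def __init__(self, m):
                self.m = m

        fit = lambda X, y: MeanModel(y.mean())
        predict = lambda model, X: np.full(X.shape[0], model.m)
        pred = loocv(fit, predict, np.zeros((3, 1)), np.array([0.0, 0.0, 3.0]))
        np.testing.assert_allclose(pred.y_pred, [1.5, 1.5, 0.0])
        assert rmse(pred) == pytest.approx(np.sqrt(4.5), abs=1e-9)

    def test_prediction_count_and_order(self, rng):
        X = rng.random((12, 4))
        y = rng.random(12)
        fit = lambda A, b: pls_fit(A, b, 2)
        pred = loocv(fit, pls_predict, X, y)
        assert pred.n == 12
        np.testing.assert_array_equal(pred.y_true, y)

    def test_permutation_invariance_of_pooled_metrics(self, rng):
        X = rng.random((15, 5))
        y = rng.random(15)
        fit = lambda A, b: pls_fit(A, b, 2)
        perm = rng.permutation(15)
        a = loocv(fit, pls_predict, X, y)
        b = loocv(fit, pls_predict, X[perm], y[perm])
        assert rmse(a) == pytest.approx(rmse(b), abs=1e-10)

    def test_held_out_response_never_leaks(self, rng):
        # with an OSC chain: changing y[i] must not change prediction i
        X = rng.random((15, 12))
        y = rng.random(15)
        fit = lambda A, b: pls_fit(A, b, 3)
        base = loocv(fit, pls_predict, X, y, chain="osc + 1st derivative")
        y2 = y.copy()
        y2[4] += 100.0
        bumped = loocv(fit, pls_predict, X, y2, chain="osc + 1st derivative")
        assert bumped.y_pred[4] == pytest.approx(base.y_pred[4], abs=1e-9)


class TestSplit:
    def test_210_samples_split_147_63(self):
        train, test = split_70_30(210, seed=0)
        assert train.size == 147 and test.size == 63

    def test_partition_properties(self):
        train, test = split_70_30(50, seed=3)
        assert np.intersect1d(train, test).size == 0
        np.testing.assert_array_equal(np.union1d(train, test), np.arange(50))

    def test_seed_reproducibility(self):
        assert np.array_equal(split_70_30(100, 5)[0], split_70_30(100, 5)[0])

    def test_stratified_split_balances_groups(self):
        day = np.repeat([0, 7, 14], 30)
        train, test = split_70_30(90, seed=1, stratify=day)
        for level in (0, 7, 14):
            assert (day[train] == level).sum() == 21

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_70_30(5, seed=0)


class TestEvaluateSplit:
    def test_rpd_consistent_with_its_own_parts(self, small_dataset):
        dataset, _, _ = small_dataset
        fit = lambda A, b: pls_fit(A, b, min(5, A.shape[0] - 1))
        train, test = split_70_30(dataset.n_samples, seed=2)
        metrics, _, pred = evaluate_split(
            fit, pls_predict, dataset.X, dataset.y, train, test, chain="1st derivative"
        )
        assert metrics.rpd == pytest.approx(metrics.sd_p / metrics.rmse_p, abs=1e-9)
        assert metrics.rmse_p == pytest.approx(rmse(pred))
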