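"""GRNN correctness against a literal kernel-average transcription, its
limit behaviors, SVR/RF contracts, and grid-search tuning."""

import numpy as np
import pytest

from fmgforce import (
    GRNN,
    ConfigError,
    DataError,
    RFConfig,
    SVRConfig,
    TuningPlan,
    grnn_fit,
    grnn_predict,
    rf_fit_predict,
    svr_fit_predict,
    tune,
)
from fmgforce.regression import fold_indices, make_regressor


def literal_grnn(X, Y, sigma, Xq):
    """Direct transcription of the kernel-average definition (the oracle)."""
    X, Y, Xq = np.asarray(X, float), np.asarray(Y, float), np.asarray(Xq, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    out = np.zeros((Xq.shape[0], Y.shape[1]))
    for q in range(Xq.shape[0]):
        num = np.zeros(Y.shape[1])
        den = 0.0
        for i in range(X.shape[0]):
            d2 = float((Xq[q] - X[i]) @ (Xq[q] - X[i]))
            w = np.exp(-d2 / (2 * sigma**2))
            num += w * Y[i]
            den += w
        out[q] = num / den
    return out


class TestGRNN:
    def test_pattern_units_equal_training_samples(self, rng):
        X = rng.normal(size=(37, 4))
        m = grnn_fit(X, rng.normal(size=37), sigma=0.5)
        assert m.n_pattern_units == 37

    def test_fit_deterministic(self, rng):
        X, Y = rng.normal(size=(20, 3)), rng.normal(size=(20, 2))
        a = grnn_predict(grnn_fit(X, Y, 0.7), X[:5])
        b = grnn_predict(grnn_fit(X, Y, 0.7), X[:5])
        assert np.array_equal(a, b)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ConfigError):
            GRNN(sigma=0.0)

    def test_single_training_sample_returns_its_label(self, rng):
        m = grnn_fit(np.array([[4.0, -1.0]]), np.array([3.7]), sigma=2.0)
        pred = grnn_predict(m, rng.normal(size=(5, 2)) * 10)
        assert np.allclose(pred, 3.7)

    def test_hand_worked_two_point_example(self):
        # patterns {0, 1} with outputs {0, 2}, sigma 1, query 0:
        # (0 + 2 e^-0.5) / (1 + e^-0.5)
        m = grnn_fit(np.array([[0.0], [1.0]]), np.array([0.0, 2.0]), sigma=1.0)
        expected = 2 * np.exp(-0.5) / (1 + np.exp(-0.5))
        assert grnn_predict(m, np.array([[0.0]]))[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7551, abs=1e-4)

    def test_equidistant_query_averages_labels(self):
        m = grnn_fit(np.array([[-1.0], [1.0]]), np.array([2.0, 6.0]), sigma=0.8)
        assert grnn_predict(m, np.array([[0.0]]))[0, 0] == pytest.approx(4.0, abs=1e-12)

    def test_matches_literal_transcription(self, rng):
        for trial in range(3):
            n, d, k = 40, 5, 2
            X = rng.normal(size=(n, d))
            Y = rng.normal(size=(n, k))
            Xq = rng.normal(size=(15, d))
            for sigma in (0.3, 1.0, 4.0):
                fast = grnn_predict(grnn_fit(X, Y, sigma), Xq)
                assert np.allclose(fast, literal_grnn(X, Y, sigma, Xq), atol=1e-10)

    def test_predictions_are_convex_combinations(self, rng):
        X, Y = rng.normal(size=(50, 3)), rng.normal(size=(50, 2))
        pred = grnn_predict(grnn_fit(X, Y, 0.2), rng.normal(size=(30, 3)) * 3)
        for j in range(2):
            assert np.all(pred[:, j] >= Y[:, j].min() - 1e-12)
            assert np.all(pred[:, j] <= Y[:, j].max() + 1e-12)

    def test_large_sigma_limit_is_training_mean(self, rng):
        X, Y = rng.uniform(size=(60, 4)), rng.uniform(size=(60, 2))
        pred = grnn_predict(grnn_fit(X, Y, 1e6), rng.uniform(size=(10, 4)))
        assert np.allclose(pred, Y.mean(axis=0), atol=1e-6)

    def test_underflow_far_query_returns_nearest_pattern_label(self):
        # kernels underflow at this distance/sigma; stabilization leaves
        # the nearest pattern with weight 1
        X = np.array([[0.0], [100.0]])
        Y = np.array([1.0, 9.0])
        pred = grnn_predict(grnn_fit(X, Y, 1e-3), np.array([[99.0]]))
        assert pred[0, 0] == pytest.approx(9.0)
        assert np.isfinite(pred).all()

    def test_dimension_mismatch_rejected(self, rng):
        m = grnn_fit(rng.normal(size=(10, 3)), rng.normal(size=10), 1.0)
        with pytest.raises(DataError):
            grnn_predict(m, rng.normal(size=(5, 4)))

    def test_empty_training_rejected(self):
        with pytest.raises(DataError):
            grnn_fit(np.empty((0, 3)), np.empty(0), 1.0)


class TestSVR:
    def test_constant_target_predicted_within_tube(self, rng):
        X = rng.normal(size=(60, 4))
        pred = svr_fit_predict(SVRConfig(nu=0.5, c=1.0), X, np.full(60, 2.5), X)
        assert np.allclose(pred, 2.5, atol=1e-3)

    def test_linear_target_high_heldout_r2(self, rng):
        from fmgforce import r_squared

        w = np.array([1.0, -2.0, 0.5])
        X = rng.normal(size=(500, 3))
        y = X @ w + 0.01 * rng.normal(size=500)
        Xq = rng.normal(size=(200, 3))
        yq = Xq @ w
        pred = svr_fit_predict(SVRConfig(nu=0.5, c=10.0, sigma_rbf="scale"), X, y, Xq)
        assert r_squared(yq, pred) >= 0.95

    def test_duplicate_rows_leave_finite_predictions(self, rng):
        X = np.repeat(rng.normal(size=(5, 2)), 10, axis=0)
        y = np.repeat(rng.normal(size=5), 10)
        pred = svr_fit_predict(SVRConfig(), X, y, X)
        assert np.all(np.isfinite(pred))

    def test_invalid_nu_rejected(self):
        with pytest.raises(ConfigError):
            SVRConfig(nu=1.5)


class TestRF:
    def test_single_unbounded_tree_interpolates_training(self, rng):
        # one tree, no bootstrap: distinct inputs are memorized exactly
        from sklearn.ensemble import RandomForestRegressor

        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        tree = RandomForestRegressor(
            n_estimators=1, bootstrap=False, max_features=1.0, random_state=0
        )
        tree.fit(X, y)
        assert np.allclose(tree.predict(X), y)

    def test_prediction_is_mean_of_trees(self, rng):
        from sklearn.ensemble import RandomForestRegressor

        X = rng.normal(size=(80, 4))
        y = X[:, 0] + rng.normal(scale=0.1, size=80)
        rf = RandomForestRegressor(n_estimators=25, random_state=1, n_jobs=1)
        rf.fit(X, y)
        Xq = rng.normal(size=(20, 4))
        manual = np.mean([t.predict(Xq) for t in rf.estimators_], axis=0)
        assert np.allclose(rf.predict(Xq), manual, atol=1e-12)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        Xq = rng.normal(size=(10, 3))
        a = rf_fit_predict(RFConfig(n_trees=10), X, y, Xq, seed=5)
        b = rf_fit_predict(RFConfig(n_trees=10), X, y, Xq, seed=5)
        assert np.array_equal(a, b)

    def test_zero_trees_rejected(self):
        with pytest.raises(ConfigError):
            RFConfig(n_trees=0)


class TestTuning:
    def test_single_point_grid_returned(self, rng):
        plan = TuningPlan(grids={"grnn": [{"sigma": 0.42}]})
        X, Y = rng.normal(size=(30, 2)), rng.normal(size=30)
        assert tune(plan, "grnn", X, Y) == {"sigma": 0.42}

    def test_interior_sigma_on_smooth_noiseless_target(self):
        # brute-force re-scoring is the oracle for the tuner's selection
        x = np.linspace(0, 3, 120)[:, None]
        y = np.sin(2 * x[:, 0])
        grid = [{"sigma": s} for s in np.logspace(-2, 0, 5)]
        plan = TuningPlan(grids={"grnn": grid}, seed=3)
        best = tune(plan, "grnn", x, y)
        sigmas = [g["sigma"] for g in grid]
        assert best["sigma"] not in (sigmas[0], sigmas[-1])

        from fmgforce.regression import _score_grnn_grid

        folds = fold_indices(len(x), 10, 3)
        scores = _score_grnn_grid(grid, folds, x, y[:, None])
        assert best["sigma"] == sigmas[int(np.argmin(scores))]

    def test_tuning_deterministic(self, rng):
        X, Y = rng.normal(size=(60, 3)), rng.normal(size=60)
        plan = TuningPlan(grids={"grnn": [{"sigma": s} for s in (0.1, 0.5, 1.0)]}, seed=9)
        assert tune(plan, "grnn", X, Y) == tune(plan, "grnn", X, Y)

    def test_tie_breaks_toward_smoothest(self, rng):
        # constant target: every sigma scores identically; largest wins
        X = rng.normal(size=(40, 2))
        Y = np.full(40, 1.0)
        plan = TuningPlan(grids={"grnn": [{"sigma": s} for s in (0.1, 0.5, 1.0)]})
        assert tune(plan, "grnn", X, Y)["sigma"] == 1.0

    def test_empty_grid_rejected(self, rng):
        plan = TuningPlan(grids={"grnn": []})
        with pytest.raises(ConfigError):
            tune(plan, "grnn", rng.normal(size=(30, 2)), rng.normal(size=30))

    def test_folds_partition_samples(self):
        folds = fold_indices(53, 10, seed=1)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(53))
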