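import numpy as np
import pytest

from brainmux import (
    BaselineConfig,
    DnnConfig,
    fit_baseline,
    fit_dnn,
    grid_search,
    repeated_kfold,
)


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((500, 20))
    beta = rng.standard_normal(20)
    return X, X @ beta


class TestDnn:
    def test_constant_target(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 5))
        model = fit_dnn(X, np.full(100, 37.0), DnnConfig(hidden_sizes=(16, 8), seed=0))
        np.testing.assert_allclose(model.predict(X), 37.0, atol=1e-3)

    def test_recovers_noiseless_linear_signal(self, linear_problem):
        X, y = linear_problem
        # least-squares oracle: the signal is exactly recoverable
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8
        model = fit_dnn(X, y, DnnConfig(seed=0))
        assert np.mean(np.abs(model.predict(X) - y)) < 0.5

    def test_default_layer_sizes(self, linear_problem):
        X, y = linear_problem
        model = fit_dnn(X[:50], y[:50], DnnConfig(epochs=5, early_stopping=False))
        assert model.layer_sizes == (20, 200, 100, 50, 20, 1)
        assert len(model.coefs) == 5  # four hidden layers + output

    def test_rejects_nonfinite_input(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_dnn(X, np.arange(10.0), DnnConfig(hidden_sizes=(4, 2)))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="two hidden"):
            DnnConfig(hidden_sizes=(10,))
        with pytest.raises(ValueError, match="activation"):
            DnnConfig(activation="maxout")
        with pytest.raises(ValueError, match="L1"):
            DnnConfig(l1=0.5)


class TestBaselines:
    def test_ridge_lambda_zero_is_ols(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.normal(0, 0.1, 60) + 5.0
        ridge = fit_baseline(X, y, BaselineConfig(kind="ridge", lam=0.0))
        Xc = np.column_stack([np.ones(60), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(ridge.coef_, beta[1:], atol=1e-6)

    def test_lasso_large_lambda_is_null_model(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 5))
        y = rng.normal(10.0, 2.0, 50)
        lasso = fit_baseline(X, y, BaselineConfig(kind="lasso", lam=1e6))
        np.testing.assert_allclose(lasso.coef_, 0.0)
        assert lasso.intercept_ == pytest.approx(y.mean())

    def test_ridge_closed_form(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 3))
        y = rng.standard_normal(5)
        lam = 2.5
        ridge = fit_baseline(X, y, BaselineConfig(kind="ridge", lam=lam))
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(3), Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(ridge.coef_, beta, atol=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            BaselineConfig(kind="boosting")

    @pytest.mark.parametrize("kind", ["rf", "svm"])
    def test_ensemble_and_svm_expose_predict(self, kind):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 3))
        y = X[:, 0] * 2.0
        model = fit_baseline(X, y, BaselineConfig(kind=kind, n_trees=20))
        assert model.predict(X).shape == (40,)

    def test_penalty_path_monotone_coefficient_norm(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((80, 6))
        y = X @ rng.standard_normal(6) + rng.normal(0, 0.5, 80)
        for kind, ord_ in (("ridge", 2), ("lasso", 1)):
            norms = [
                np.linalg.norm(
                    fit_baseline(X, y, BaselineConfig(kind=kind, lam=lam)).coef_, ord_
                )
                for lam in (0.01, 0.1, 1.0, 10.0)
            ]
            assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


class TestGridSearch:
    def test_singleton_grid(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 3))
        y = X[:, 0]
        best, table = grid_search(X, y, BaselineConfig(kind="ridge"), {"lam": [0.5]})
        assert best.lam == 0.5
        assert len(table) == 1

    def test_strong_signal_prefers_small_lambda(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 5))
        y = X @ np.array([3.0, -2.0, 1.0, 4.0, -1.0])
        best, _ = grid_search(
            X, y, BaselineConfig(kind="ridge"), {"lam": [0.01, 1e6]}, seed=0
        )
        assert best.lam == 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 4))
        y = X[:, 0] + rng.normal(0, 0.5, 50)
        grids = {"lam": [0.1, 1.0, 10.0]}
        b1, t1 = grid_search(X, y, BaselineConfig(kind="ridge"), grids, seed=3)
        b2, t2 = grid_search(X, y, BaselineConfig(kind="ridge"), grids, seed=3)
        assert b1.lam == b2.lam
        assert t1.equals(t2)

    def test_empty_grid_error(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search(np.ones((10, 2)), np.ones(10), BaselineConfig(kind="ridge"), {})


class TestRepeatedKFold:
    def test_leave_one_out_structure(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 3))
        y = X[:, 0]
        res = repeated_kfold(X, y, BaselineConfig(kind="ridge"), k=12, repetitions=1)
        assert res.predictions.shape == (1, 12)
        assert len(np.unique(res.fold_assignments)) == 12

    def test_fold_size_partition_484_by_10(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((484, 3))
        y = rng.uniform(7, 80, 484)
        res = repeated_kfold(X, y, BaselineConfig(kind="ridge"), k=10, repetitions=1)
        sizes = np.bincount(res.fold_assignments[0])
        assert set(sizes.tolist()) == {48, 49}
        assert sizes.sum() == 484

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((40, 4))
        y = X[:, 0] + rng.normal(0, 0.2, 40)
        r1 = repeated_kfold(X, y, BaselineConfig(kind="ridge"), k=5, repetitions=2, seed=7)
        r2 = repeated_kfold(X, y, BaselineConfig(kind="ridge"), k=5, repetitions=2, seed=7)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_sample_smaller_than_k_error(self):
        with pytest.raises(ValueError, match="smaller than k"):
            repeated_kfold(np.ones((5, 2)), np.ones(5), BaselineConfig(kind="ridge"), k=10)

    def test_every_subject_predicted_once_per_repetition(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((23, 3))
        y = X[:, 0]
        res = repeated_kfold(X, y, BaselineConfig(kind="ridge"), k=4, repetitions=3)
        assert np.all(np.isfinite(res.predictions))
        sizes = np.array([np.bincount(f) for f in res.fold_assignments])
        assert np.all(sizes.max(axis=1) - sizes.min(axis=1) <= 1)

    def test_long_table_shape(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((20, 2))
        y = X[:, 0]
        res = repeated_kfold(X, y, BaselineConfig(kind="ridge"), k=4, repetitions=2)
        df = res.to_frame()
        assert len(df) == 40
        assert set(df.columns) == {"subject", "repetition", "fold", "y", "yhat"}
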