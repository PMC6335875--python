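"""Elastic-net / ridge solver: closed-form oracles, KKT optimality, warm
starts, and agreement with an independent solver."""

import numpy as np
import pandas as pd
import pytest

from sleepdebt.penalized import (
    PenalizedModel,
    PenalizedRegression,
    fit,
    lambda_grid,
    soft_threshold,
)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,g,expected",
        [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.7, 0.0, 0.7)],
    )
    def test_values(self, z, g, expected):
        assert soft_threshold(z, g) == pytest.approx(expected)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestFullShrinkage:
    def test_linear_reduces_to_mean(self, regression_problem):
        X, y, _ = regression_problem
        m = fit(X, y, family="linear", alpha=0.5, lam=1e6)
        assert np.all(m.coef == 0.0)
        assert m.intercept == pytest.approx(y.mean())
        assert m.nonzero_panel() == []

    def test_logistic_reduces_to_log_odds(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.array([1] * 25 + [0] * 15)
        m = fit(X, y, family="logistic", alpha=0.5, lam=1e6)
        assert np.all(m.coef == 0.0)
        assert m.intercept == pytest.approx(np.log(25 / 15), abs=1e-5)


class TestClosedForms:
    def test_orthonormal_single_feature_soft_threshold(self, rng):
        """Single standardized feature: beta = S(b_ols, lam*alpha)/(1 + lam*(1-alpha))."""
        n = 200
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 1.3 * x + rng.normal(size=n)
        b_ols = float(x @ (y - y.mean())) / n
        for lam in (0.05, 0.5, 2.0):
            m = PenalizedRegression(y, x[:, None], family="linear", alpha=0.5).fit(lam, tol=1e-12)
            expected = soft_threshold(b_ols, lam * 0.5) / (1 + lam * 0.5)
            assert m.coef_std[0] == pytest.approx(expected, abs=1e-6)

    def test_feature_below_threshold_excluded(self, rng):
        n = 200
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 0.1 * x + rng.normal(size=n)
        b_ols = float(x @ (y - y.mean())) / n
        lam = 2.1 * abs(b_ols)  # lam*alpha > |b_ols|
        m = PenalizedRegression(y, x[:, None], family="linear", alpha=0.5).fit(lam)
        assert m.nonzero_panel() == []

    def test_ridge_matches_closed_form(self, rng):
        n, p = 60, 8
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        Xs = (X - X.mean(0)) / X.std(0)
        for lam in (0.1, 1.0, 5.0):
            m = PenalizedRegression(y, X, family="linear", alpha=0.0).fit(lam, tol=1e-12)
            ref = np.linalg.solve(Xs.T @ Xs / n + lam * np.eye(p), Xs.T @ (y - y.mean()) / n)
            assert np.abs(m.coef_std - ref).max() < 1e-6

    def test_ridge_selects_all_features(self, rng):
        """alpha=0 performs no selection: the panel is every feature."""
        n, p = 50, 10
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)  # pure noise
        m = PenalizedRegression(y, X, family="linear", alpha=0.0).fit(0.5, tol=1e-10)
        assert len(m.nonzero_panel()) == p


class TestKKT:
    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_subgradient_optimality_random_problems(self, family):
        """|(1/n)<x_j, resid> - lam(1-a)b_j| <= lam*a at zeros, equality with
        sign at nonzeros; violations < 1e-5 on 50 random 20-feature problems."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            n, p = 40, 20
            X = rng.normal(size=(n, p))
            beta = np.zeros(p)
            beta[:3] = rng.normal(size=3)
            if family == "linear":
                y = X @ beta + rng.normal(size=n)
            else:
                y = (X @ beta + rng.logistic(size=n) > 0).astype(float)
                if y.min() == y.max():
                    continue
            lam = float(rng.uniform(0.01, 0.5))
            model = PenalizedRegression(y, X, family=family, alpha=0.5)
            res = model.fit(lam, tol=1e-10)
            worst = max(worst, float(model.kkt_residuals(res).max()))
        assert worst < 1e-5

    def test_objective_non_increasing_per_sweep(self, regression_problem):
        X, y, _ = regression_problem
        model = PenalizedRegression(y, X, family="linear", alpha=0.5)
        res = model.fit(0.1, track_objective=True)
        hist = res.objective_path
        assert hist is not None and len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-12)


class TestLambdaGrid:
    def test_null_model_at_lambda_max(self, regression_problem):
        X, y, _ = regression_problem
        grid = lambda_grid(X, y, family="linear", alpha=0.5, n_lambda=10)
        m = fit(X, y, family="linear", alpha=0.5, lam=grid[0])
        assert m.nonzero_panel() == []

    def test_grid_shape_and_monotonicity(self, regression_problem):
        X, y, _ = regression_problem
        grid = lambda_grid(X, y, family="linear", alpha=0.5, n_lambda=37, ratio=1e-3)
        assert len(grid) == 37
        assert np.all(np.diff(grid) < 0)

    def test_halving_ratio_extends_lower_end_only(self, regression_problem):
        X, y, _ = regression_problem
        g1 = lambda_grid(X, y, alpha=0.5, n_lambda=10, ratio=1e-2)
        g2 = lambda_grid(X, y, alpha=0.5, n_lambda=10, ratio=5e-3)
        assert g1[0] == pytest.approx(g2[0])
        assert g2[-1] < g1[-1]


class TestPath:
    def test_warm_start_matches_cold_start(self, regression_problem):
        X, y, _ = regression_problem
        model = PenalizedRegression(y, X, family="linear", alpha=0.5)
        grid = model.lambda_grid(n_lambda=20, ratio=1e-2)
        path = model.fit_path(grid, tol=1e-10)
        for lam, warm_model in zip(grid[::5], path.models[::5]):
            cold = model.fit(lam, tol=1e-10)
            assert np.abs(cold.coef_std - warm_model.coef_std).max() < 1e-6

    def test_grid_must_decrease(self):
        from sleepdebt.penalized import LambdaPath

        with pytest.raises(ValueError):
            LambdaPath(np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            LambdaPath(np.array([0.5]))


class TestPredict:
    def test_zero_model_logistic_gives_half(self):
        m = PenalizedModel(intercept=0.0, coef=np.zeros(3), feature_names=["a", "b", "c"],
                           family="logistic", alpha=0.5, lam=1.0, means=np.zeros(3),
                           sds=np.ones(3), converged=True, n_sweeps=0, n_obs=10,
                           coef_std=np.zeros(3))
        assert np.allclose(m.predict(np.random.default_rng(0).normal(size=(5, 3))), 0.5)

    def test_constant_linear_model(self):
        m = PenalizedModel(intercept=24.0, coef=np.zeros(2), feature_names=["a", "b"],
                           family="linear", alpha=0.5, lam=1.0, means=np.zeros(2),
                           sds=np.ones(2), converged=True, n_sweeps=0, n_obs=10,
                           coef_std=np.zeros(2))
        assert np.allclose(m.predict(np.ones((4, 2))), 24.0)

    def test_monotone_in_positive_coefficient(self, regression_problem):
        X, y, _ = regression_problem
        m = fit(X, y, family="linear", alpha=0.5, lam=0.05)
        j = int(np.argmax(m.coef))
        assert m.coef[j] > 0
        x0 = X[0].copy()
        x1 = x0.copy()
        x1[j] += 1.0
        assert m.predict(x1[None, :])[0] > m.predict(x0[None, :])[0]

    def test_missing_features_listed(self, regression_problem):
        X, y, _ = regression_problem
        Xdf = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        m = fit(Xdf, y, family="linear", alpha=0.5, lam=0.1)
        with pytest.raises(ValueError, match="f0"):
            m.predict(Xdf.drop(columns=["f0"]))


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, regression_problem):
        X, y, _ = regression_problem
        m = fit(X, y, family="linear", alpha=0.5, lam=0.1)
        path = tmp_path / "model.tsv"
        m.to_tsv(path)
        back = PenalizedModel.from_tsv(path)
        assert back.family == "linear"
        assert back.lam == m.lam
        assert np.allclose(back.coef, m.coef)
        assert np.allclose(back.predict(X), m.predict(X))


class TestAgainstIndependentSolver:
    def test_linear_matches_sklearn_elastic_net(self, rng):
        """Same objective convention as scikit-learn's ElasticNet on
        pre-standardized data; agreement within 1e-4."""
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        n, p = 80, 20
        X = rng.normal(size=(n, p))
        y = X[:, 0] * 2 - X[:, 1] + rng.normal(size=n)
        Xs = (X - X.mean(0)) / X.std(0)
        for lam in (0.05, 0.3):
            ours = PenalizedRegression(y, Xs, family="linear", alpha=0.5).fit(lam, tol=1e-12)
            ref = sklearn_linear.ElasticNet(alpha=lam, l1_ratio=0.5, tol=1e-12,
                                            max_iter=100000).fit(Xs, y)
            assert np.abs(ours.coef_std - ref.coef_).max() < 1e-4

    def test_logistic_matches_sklearn_saga(self, rng):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        n, p = 120, 8
        X = rng.normal(size=(n, p))
        y = (X[:, 0] - X[:, 1] + rng.logistic(size=n) > 0).astype(int)
        Xs = (X - X.mean(0)) / X.std(0)
        lam = 0.05
        ours = PenalizedRegression(y, Xs, family="logistic", alpha=0.5).fit(lam, tol=1e-12)
        ref = sklearn_linear.LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=0.5, C=1.0 / (n * lam),
            tol=1e-10, max_iter=200000,
        ).fit(Xs, y)
        assert np.abs(ours.coef_std - ref.coef_[0]).max() < 1e-4
        assert ours.intercept - float(ours.coef @ np.zeros(p)) == pytest.approx(
            float(ref.intercept_[0]), abs=1e-3
        )


def test_single_class_logistic_rejected(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError, match="two classes"):
        PenalizedRegression(np.ones(10), X, family="logistic")


def test_summary_mentions_panel(regression_problem):
    X, y, _ = regression_problem
    m = fit(X, y, family="linear", alpha=0.5, lam=0.05)
    text = m.summary()
    assert "panel size" in text
    assert "lambda" in text
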