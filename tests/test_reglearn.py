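import math

import numpy as np
import pytest
from scipy.optimize import minimize

from eegcomplex import (
    fit_penalized_lr,
    lambda_path,
    penalized_objective,
    predict_proba,
    select_lambda_nested,
)
from eegcomplex.reglearn import _grouped_folds


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(0)
    n, p = 80, 20
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[:3] = [1.5, -1.0, 0.8]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-X @ beta))).astype(float)
    return X, y


def reference_objective(beta0, beta, X, y, lam, alpha):
    """Direct term-by-term transcription of the penalized log-likelihood."""
    total = 0.0
    for i in range(len(y)):
        eta = beta0 + float(np.dot(beta, X[i]))
        total += y[i] * eta - math.log(1.0 + math.exp(eta))
    pen = sum((1.0 - alpha) * b * b + alpha * abs(b) for b in beta)
    return total - lam * pen


class TestObjective:
    def test_zero_model(self, instance):
        X, y = instance
        assert penalized_objective(0.0, np.zeros(X.shape[1]), X, y, 3.0, 0.5) == (
            pytest.approx(-len(y) * math.log(2.0))
        )

    def test_alpha_one_is_lasso(self, instance):
        X, y = instance
        rng = np.random.default_rng(1)
        beta = rng.standard_normal(X.shape[1])
        lasso = penalized_objective(0.3, beta, X, y, 2.0, 1.0)
        eta = 0.3 + X @ beta
        eq3 = float(np.sum(y * eta - np.log1p(np.exp(eta)))) - 2.0 * np.abs(beta).sum()
        assert lasso == pytest.approx(eq3, rel=1e-12)

    def test_matches_reference_transcription(self, instance):
        X, y = instance
        rng = np.random.default_rng(2)
        for _ in range(5):
            beta = rng.standard_normal(X.shape[1]) * 0.3
            beta0 = float(rng.standard_normal())
            lam = float(rng.uniform(0, 5))
            alpha = float(rng.uniform(0, 1))
            assert penalized_objective(beta0, beta, X, y, lam, alpha) == pytest.approx(
                reference_objective(beta0, beta, X, y, lam, alpha), rel=1e-10
            )

    def test_rejects_nonbinary_y(self, instance):
        X, _ = instance
        with pytest.raises(ValueError):
            penalized_objective(0.0, np.zeros(X.shape[1]), X, np.full(X.shape[0], 2.0), 1.0, 1.0)


class TestFit:
    def test_null_model_at_lambda_max(self, instance):
        X, y = instance
        lam_max = lambda_path(X, y, 0.7)[0]
        model = fit_penalized_lr(X, y, lam_max, 0.7, tol=1e-10)
        assert np.all(model.beta == 0.0)
        assert model.beta0 == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_unpenalized_matches_convex_oracle(self, instance):
        X, y = instance
        model = fit_penalized_lr(X, y, 0.0, 1.0)
        assert model.converged

        def nll(c):
            eta = c[0] + X @ c[1:]
            return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

        res = minimize(nll, np.zeros(X.shape[1] + 1), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 5000})
        np.testing.assert_allclose(
            np.r_[model.beta0, model.beta], res.x, rtol=0, atol=1e-6
        )

    def test_lasso_matches_sklearn(self, instance):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = instance
        lam = 4.0
        model = fit_penalized_lr(X, y, lam, 1.0, tol=1e-9)
        skl = sklearn.LogisticRegression(
            penalty="l1", C=1.0 / lam, solver="liblinear", tol=1e-10,
            max_iter=10_000, intercept_scaling=1e6,
        ).fit(X, y)
        np.testing.assert_allclose(model.beta, skl.coef_.ravel(), rtol=0, atol=1e-4)

    def test_alpha_continuity_at_one(self, instance):
        X, y = instance
        a = fit_penalized_lr(X, y, 1.0, 1.0, tol=1e-9)
        b = fit_penalized_lr(X, y, 1.0, 1.0 - 1e-12, tol=1e-9)
        assert np.abs(a.beta - b.beta).max() < 1e-6

    @pytest.mark.parametrize("lam,alpha", [(5.0, 1.0), (5.0, 0.7), (0.5, 0.3), (0.5, 1.0)])
    @pytest.mark.parametrize("solver", ["cd", "fista"])
    def test_kkt_and_monotone_objective(self, instance, lam, alpha, solver):
        X, y = instance
        tol = 1e-8
        model = fit_penalized_lr(X, y, lam, alpha, tol=tol, solver=solver)
        assert model.converged
        assert model.kkt_residual <= tol
        assert np.all(np.diff(model.objective_path) >= -1e-12)

    def test_solvers_agree(self, instance):
        X, y = instance
        a = fit_penalized_lr(X, y, 2.0, 0.7, tol=1e-10, solver="cd")
        b = fit_penalized_lr(X, y, 2.0, 0.7, tol=1e-10, solver="fista")
        np.testing.assert_allclose(a.beta, b.beta, rtol=0, atol=1e-7)

    def test_single_class_rejected(self, instance):
        X, _ = instance
        with pytest.raises(ValueError):
            fit_penalized_lr(X, np.zeros(X.shape[0]), 1.0, 1.0)

    def test_separable_unpenalized_warns_and_overfits(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 100))  # p >> n: linearly separable
        y = np.r_[np.zeros(15), np.ones(15)]
        with pytest.warns(RuntimeWarning, match="separable"):
            model = fit_penalized_lr(X, y, 0.0, 1.0, max_iter=100)
        assert not model.converged
        acc = np.mean((predict_proba(model, X) >= 0.5) == y.astype(bool))
        assert acc == 1.0


class TestLambdaPath:
    def test_contract(self, instance):
        X, y = instance
        grid = lambda_path(X, y, 0.7, K=50)
        assert len(grid) == 50
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] == pytest.approx(1e-3 * grid[0])

    def test_zero_active_at_endpoint(self, instance):
        X, y = instance
        grid = lambda_path(X, y, 1.0)
        model = fit_penalized_lr(X, y, grid[0], 1.0, tol=1e-10)
        assert len(model.active_set) == 0

    def test_active_set_grows_from_endpoint_to_endpoint(self, instance):
        X, y = instance
        grid = lambda_path(X, y, 1.0, K=20)
        sizes = []
        b0, b = None, None
        for lam in grid:
            m = fit_penalized_lr(X, y, lam, 1.0, tol=1e-7, beta0_init=b0, beta_init=b)
            b0, b = m.beta0, m.beta
            sizes.append(len(m.active_set))
        assert sizes[0] == 0
        assert sizes[-1] == max(sizes)

    def test_alpha_zero_rejected(self, instance):
        X, y = instance
        with pytest.raises(ValueError):
            lambda_path(X, y, 0.0)


class TestNestedSelection:
    def test_grouping_contract(self):
        rng = np.random.default_rng(0)
        groups = np.repeat([f"s{i}" for i in range(20)], 3)
        y = np.repeat(np.r_[np.zeros(10), np.ones(10)], 3)
        folds = _grouped_folds(groups, y, 5, rng)
        assert sorted(np.concatenate(folds).tolist()) == list(range(60))
        for fold in folds:
            fold_subjects = set(groups[fold])
            other = set(groups) - fold_subjects
            # no subject straddles the fold boundary
            assert not fold_subjects & set(groups[np.setdiff1d(np.arange(60), fold)]) - other

    def test_sessions_never_straddle(self):
        rng = np.random.default_rng(1)
        groups = np.repeat([f"s{i}" for i in range(12)], 3)
        y = np.repeat(np.r_[np.zeros(6), np.ones(6)], 3)
        folds = _grouped_folds(groups, y, 3, rng)
        for fold in folds:
            train = np.setdiff1d(np.arange(36), fold)
            assert not set(groups[fold]) & set(groups[train])

    def test_deterministic_given_seed(self, instance):
        X, y = instance
        groups = np.array([f"s{i // 4}" for i in range(len(y))])
        a = select_lambda_nested(X, y, groups, 0.7, seed=5)
        b = select_lambda_nested(X, y, groups, 0.7, seed=5)
        assert a == b

    def test_strong_signal_interior_lambda(self):
        rng = np.random.default_rng(7)
        n, p = 120, 30
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        beta = np.zeros(p)
        beta[:4] = [2.0, -2.0, 1.5, 1.0]
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-X @ beta))).astype(float)
        groups = np.array([f"s{i // 2}" for i in range(n)])
        grid = lambda_path(X, y, 1.0)
        lam = select_lambda_nested(X, y, groups, 1.0, seed=0)
        assert grid[-1] < lam < grid[0]

    def test_too_few_subjects(self, instance):
        X, y = instance
        groups = np.array(["a" if v == 0 else "b" for v in y])
        with pytest.raises(ValueError):
            select_lambda_nested(X, y, groups, 1.0, inner_folds=5)


class TestPredictProba:
    def test_zero_model_half(self, instance):
        X, y = instance
        model = fit_penalized_lr(X, y, 1.0, 1.0)
        model.beta0 = 0.0
        model.beta = np.zeros(X.shape[1])
        assert np.all(predict_proba(model, X) == 0.5)

    def test_open_interval_and_monotone_in_intercept(self, instance):
        X, y = instance
        model = fit_penalized_lr(X, y, 1.0, 1.0)
        p1 = predict_proba(model, X)
        assert np.all((p1 > 0) & (p1 < 1))
        model.beta0 += 1.0
        assert np.all(predict_proba(model, X) > p1)

    def test_dimension_mismatch(self, instance):
        X, y = instance
        model = fit_penalized_lr(X, y, 1.0, 1.0)
        with pytest.raises(ValueError):
            predict_proba(model, X[:, :3])
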