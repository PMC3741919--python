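"""Epsilon-SVR training against independent quadratic-programming and
library oracles, plus the KKT invariants of the dual solution."""

import numpy as np
import pytest
from scipy.optimize import minimize

from invecg.svr import (
    dual_objective,
    rbf_gram,
    rbf_kernel,
    solve_dual,
    svr_predict,
    svr_train,
)


def qp_dual_oracle(K, y, C, eps):
    """Generic box-constrained QP solve of the epsilon-SVR dual over the
    2N stacked multipliers (SLSQP with analytic gradient)."""
    n = len(y)
    Q = np.block([[K, -K], [-K, K]])
    p = np.concatenate([eps - y, eps + y])
    z = np.concatenate([np.ones(n), -np.ones(n)])
    res = minimize(
        lambda a: 0.5 * a @ Q @ a + p @ a,
        np.zeros(2 * n),
        jac=lambda a: Q @ a + p,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[{"type": "eq", "fun": lambda a: z @ a, "jac": lambda a: z}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.fun


def random_instance(rng):
    n = int(rng.integers(5, 51))
    d = int(rng.integers(1, 4))
    X = rng.normal(size=(n, d))
    y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=n)
    C = float(rng.choice([1.0, 10.0, 100.0]))
    eps = float(rng.choice([0.01, 0.05, 0.1]))
    sigma2 = float(rng.uniform(0.5, 2.0))
    return X, y, C, eps, sigma2


class TestRBFKernel:
    def test_identical_inputs_give_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert rbf_kernel(x, x, 0.7) == 1.0

    def test_distance_sqrt2sigma_gives_inverse_e(self):
        x = np.array([0.0])
        y = np.array([np.sqrt(2 * 0.8)])
        assert rbf_kernel(x, y, 0.8) == pytest.approx(np.exp(-1))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a, b = rng.normal(size=(2, 4))
            assert rbf_kernel(a, b, 1.3) == pytest.approx(rbf_kernel(b, a, 1.3))

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError, match="sigma2"):
            rbf_kernel(np.zeros(2), np.ones(2), 0.0)


class TestTraining:
    def test_constant_targets_zero_weights(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        model = svr_train(X, np.full(12, 4.2), C=10.0, sigma2=1.0, epsilon=0.05)
        assert model.beta.size == 0
        assert model.b == pytest.approx(4.2)
        np.testing.assert_allclose(svr_predict(model, X), 4.2)

    def test_line_fit_matches_qp_oracle(self):
        X = np.linspace(0.0, 1.0, 5)[:, None]
        y = X.ravel()
        model = svr_train(X, y, C=100.0, sigma2=1.0, epsilon=0.01, tol=1e-6)
        K = rbf_gram(X, X, 1.0)
        ref = qp_dual_oracle(K, y, 100.0, 0.01)
        assert abs(model.dual_obj - ref) <= 1e-4 * (1 + abs(ref))

    def test_dual_matches_qp_oracle_on_random_instances(self):
        """25 random small instances: dual objective within 1e-4 relative of
        a generic QP solution; KKT box and equality constraints hold."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            X, y, C, eps, s2 = random_instance(rng)
            model = svr_train(X, y, C, s2, eps, tol=1e-6, max_iter=2_000_000)
            ref = qp_dual_oracle(rbf_gram(X, X, s2), y, C, eps)
            assert abs(model.dual_obj - ref) <= 1e-4 * (1 + abs(ref))
            assert abs(model.beta.sum()) < 1e-6
            assert np.all(np.abs(model.beta) <= C + 1e-9)

    def test_matches_sklearn_svr(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 2))
        y = np.cos(X[:, 0]) + 0.05 * rng.normal(size=30)
        C, eps, s2 = 10.0, 0.05, 1.0
        ours = svr_train(X, y, C, s2, eps, tol=1e-6, max_iter=2_000_000)
        ref = sklearn_svm.SVR(C=C, epsilon=eps, gamma=1.0 / (2 * s2), tol=1e-6).fit(X, y)
        Xt = rng.normal(size=(15, 2))
        np.testing.assert_allclose(
            svr_predict(ours, Xt), ref.predict(Xt), atol=1e-4
        )

    def test_residual_structure(self):
        """Points violating the epsilon tube must be at-bound support
        vectors (KKT complementary slackness)."""
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, size=(25, 1))
        y = np.tanh(X.ravel())
        C, eps = 5.0, 0.05
        model = svr_train(X, y, C, 1.0, eps, tol=1e-6)
        pred = svr_predict(model, X)
        resid = np.abs(pred - y)
        sv_index = {tuple(v) for v in model.support_vectors[np.abs(model.beta) >= C - 1e-8]}
        for xi, ri in zip(X, resid):
            if ri > eps + 1e-6:
                assert tuple(xi) in sv_index

    def test_prediction_is_direct_kernel_expansion(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 2))
        y = X[:, 0] ** 2
        model = svr_train(X, y, 50.0, 0.8, 0.02)
        Xt = rng.normal(size=(6, 2))
        manual = np.array([
            sum(b * rbf_kernel(sv, xt, model.sigma2)
                for b, sv in zip(model.beta, model.support_vectors)) + model.b
            for xt in Xt
        ])
        np.testing.assert_allclose(svr_predict(model, Xt), manual, rtol=1e-12)

    def test_target_scaling_property(self):
        """Scaling targets and epsilon by k scales predictions by k."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 1))
        y = np.sin(X.ravel())
        k = 3.5
        m1 = svr_train(X, y, 10.0, 1.0, 0.02, tol=1e-8, max_iter=2_000_000)
        m2 = svr_train(X, k * y, k * 10.0, 1.0, k * 0.02, tol=1e-8, max_iter=2_000_000)
        Xt = rng.normal(size=(5, 1))
        np.testing.assert_allclose(
            svr_predict(m2, Xt), k * svr_predict(m1, Xt), atol=1e-5
        )

    def test_all_zero_beta_predicts_bias(self):
        model = svr_train(np.zeros((3, 2)) + np.eye(3, 2), np.full(3, 1.5),
                          C=1.0, sigma2=1.0, epsilon=0.5)
        assert model.beta.size == 0
        np.testing.assert_allclose(svr_predict(model, np.ones((4, 2))), 1.5)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(X=np.empty((0, 2)), y=np.empty(0)), "empty"),
            (dict(X=np.zeros((3, 1)), y=np.array([1.0, np.nan, 0.0])), "finite"),
            (dict(X=np.zeros((3, 1)), y=np.zeros(3), C=0.0), "C must"),
        ],
    )
    def test_invalid_inputs(self, kwargs, match):
        args = dict(C=1.0, sigma2=1.0, epsilon=0.1)
        args.update(kwargs)
        with pytest.raises(ValueError, match=match):
            svr_train(args["X"], args["y"], args["C"], args["sigma2"], args["epsilon"])

    def test_solve_dual_consistent_with_svr_train(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(18, 2))
        y = X[:, 1]
        K = rbf_gram(X, X, 1.2)
        beta, b, alpha = solve_dual(K, y, 10.0, 0.05, tol=1e-6)
        model = svr_train(X, y, 10.0, 1.2, 0.05, tol=1e-6)
        assert dual_objective(K, y, 0.05, alpha) == pytest.approx(model.dual_obj, rel=1e-9)
        np.testing.assert_allclose(K @ beta + b, svr_predict(model, X), atol=1e-10)
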