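"""Fitness function and the three searchers on analytic surrogates."""

import numpy as np
import pytest

from invecg.data import Hyperparameters, RunConfig
from invecg.optimizers import (
    WORST_FITNESS,
    de_search,
    evaluate_candidate,
    fitness,
    ga_search,
    make_svr_evaluator,
    pso_search,
    pso_velocity_update,
    search,
)
from invecg.optimizers import _ga_decode, _unit_to_params


# ---------------------------------------------------------------------------
# Fitness (mean absolute percentage error)
# ---------------------------------------------------------------------------


class TestFitness:
    def test_exact_predictions_zero(self):
        a = np.array([0.3, 1.7, 2.2])
        assert fitness(a, a.copy()) == 0.0

    @pytest.mark.parametrize(
        "a, p, expected",
        [([2.0], [1.0], 50.0), ([1.0, 2.0], [1.1, 1.8], 10.0)],
    )
    def test_hand_computed_values(self, a, p, expected):
        assert fitness(np.array(a), np.array(p)) == pytest.approx(expected)

    def test_near_zero_actuals_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            fitness(np.array([1.0, 1e-9]), np.array([1.0, 0.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fitness(np.ones(3), np.ones(2))


class TestEvaluateCandidate:
    def test_constant_targets_zero_fitness(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(15, 3))
        hp = Hyperparameters(10.0, 1.0, 0.01)
        assert evaluate_candidate(hp, F, np.full(15, 0.5)) == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_candidate_gets_sentinel(self):
        F = np.random.default_rng(0).normal(size=(10, 2))
        y = F[:, 0]
        assert evaluate_candidate(Hyperparameters(0.0, 1.0, 0.0), F, y) == WORST_FITNESS

    def test_near_interpolation_bounded_by_epsilon(self):
        """Large C, tiny epsilon on well-spread 1-D data: in-sample error is
        bounded by the epsilon-implied percentage."""
        X = np.linspace(0, 1, 12)[:, None]
        y = 0.2 + 0.6 * X.ravel()
        eps = 1e-4
        # sigma2 = 0.01 keeps the Gram matrix well conditioned so the solver
        # reaches the KKT tolerance; C is far above the needed coefficients
        got = evaluate_candidate(Hyperparameters(1e4, 0.01, eps), X, y, fitness_offset=1.0)
        # every residual <= eps + solver slack; offset targets >= 1.0
        bound = (eps + 1e-4) / 1.0 * 100.0
        assert got <= bound

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        F = rng.normal(size=(12, 2))
        y = np.tanh(F[:, 0])
        hp = Hyperparameters(50.0, 0.7, 1e-3)
        assert evaluate_candidate(hp, F, y) == evaluate_candidate(hp, F, y)

    def test_cv_evaluator_penalizes_vanishing_bandwidth(self):
        """Cross-validated fitness must reject the degenerate
        narrow-bandwidth interpolator that in-sample fitness rewards."""
        rng = np.random.default_rng(8)
        F = rng.normal(size=(30, 2))
        y = np.sin(F[:, 0])
        ins = make_svr_evaluator(F, y)
        cv = make_svr_evaluator(F, y, cv_folds=5)
        narrow = np.array([100.0, 1e-6, 1e-5])
        wide = np.array([100.0, 1.0, 1e-5])
        assert ins(narrow) < ins(wide)  # the in-sample pathology
        assert cv(narrow) > cv(wide)  # CV repels it


# ---------------------------------------------------------------------------
# Shared searcher behaviour on the sphere surrogate
# ---------------------------------------------------------------------------

LOWER = np.array([0.0, 0.0, 0.0])
UPPER = np.array([10000.0, 2.0, 1e-4])
USTAR = np.array([0.3, 0.6, 0.45])


def sphere(params: np.ndarray) -> float:
    """Convex surrogate on the hyperparameter box, minimum 0 at USTAR
    (unit-box coordinates)."""
    u = (params - LOWER) / (UPPER - LOWER)
    return float(np.sum((u - USTAR) ** 2))


SEARCHERS = {"ga": ga_search, "de": de_search, "pso": pso_search}


@pytest.mark.parametrize("name", ["ga", "de", "pso"])
class TestSearchersOnSphere:
    def test_converges_on_sphere(self, name):
        vals = []
        for seed in range(5):
            res = SEARCHERS[name](RunConfig(optimizer=name, seed=seed, tol=0.0), sphere)
            vals.append(res.best_fitness)
        assert np.median(vals) <= 1e-2

    def test_trajectory_monotone_and_consistent(self, name):
        res = SEARCHERS[name](RunConfig(optimizer=name, seed=3, tol=0.0), sphere)
        assert np.all(np.diff(res.trajectory) <= 0)
        assert res.trajectory[-1] == res.best_fitness
        assert res.generations == len(res.trajectory)

    def test_reproducible_bit_identical(self, name):
        cfg = RunConfig(optimizer=name, seed=7, tol=0.0)
        r1 = SEARCHERS[name](cfg, sphere)
        r2 = SEARCHERS[name](cfg, sphere)
        assert r1.best == r2.best
        assert r1.best_fitness == r2.best_fitness
        np.testing.assert_array_equal(r1.trajectory, r2.trajectory)

    def test_evaluated_candidates_stay_in_bounds(self, name):
        seen = []

        def spy(params):
            seen.append(params.copy())
            return sphere(params)

        SEARCHERS[name](RunConfig(optimizer=name, seed=1, tol=0.0), spy)
        arr = np.array(seen)
        assert np.all(arr >= LOWER - 1e-12)
        assert np.all(arr <= UPPER + 1e-12)
        # C and sigma2 repaired strictly above zero before training
        assert np.all(arr[:, :2] > 0)

    def test_evaluation_budget(self, name):
        count = {"n": 0}

        def counting(params):
            count["n"] += 1
            return sphere(params)

        cfg = RunConfig(optimizer=name, seed=2, tol=0.0)
        SEARCHERS[name](cfg, counting)
        assert count["n"] <= cfg.population * (cfg.max_iter + 1)

    def test_improves_over_initial_population(self, name):
        improved = 0
        for seed in range(20):
            traj = SEARCHERS[name](
                RunConfig(optimizer=name, seed=seed, tol=0.0), sphere
            ).trajectory
            if traj[-1] < traj[0]:
                improved += 1
        assert improved >= 19

    def test_high_tolerance_stops_after_first_evaluation(self, name):
        res = SEARCHERS[name](RunConfig(optimizer=name, seed=0, tol=1e9), sphere)
        assert res.generations == 1
        assert res.evaluations == 20

    def test_dispatch(self, name):
        cfg = RunConfig(optimizer=name, seed=5, tol=0.0)
        assert search(cfg, sphere).best_fitness == SEARCHERS[name](cfg, sphere).best_fitness


# ---------------------------------------------------------------------------
# Operator-level checks
# ---------------------------------------------------------------------------


class TestGAOperators:
    def test_decode_endpoints(self):
        bits = 20
        assert np.all(_ga_decode(np.zeros(60, dtype=np.int8), bits, 3) == 0.0)
        assert np.all(_ga_decode(np.ones(60, dtype=np.int8), bits, 3) == 1.0)

    def test_decode_monotone_in_msb(self):
        bits = 20
        c = np.zeros(60, dtype=np.int8)
        c[0] = 1  # MSB of first parameter
        u = _ga_decode(c, bits, 3)
        assert u[0] > 0.49 and u[1] == 0.0

    def test_all_failing_evaluator_aborts(self):
        def bad(params):
            return WORST_FITNESS

        with pytest.raises(RuntimeError, match="evaluator failed"):
            ga_search(RunConfig(optimizer="ga", seed=0), bad)


class TestDEOperators:
    def test_small_population_rejected(self):
        with pytest.raises(ValueError, match="6"):
            de_search(RunConfig(optimizer="de", seed=0, population=5), sphere)

    def test_F_zero_makes_mutants_equal_best(self):
        """With F forced to 0 the mutant equals x_best, so every trial gene
        drawn from the mutant equals the best candidate's gene."""
        cfg = RunConfig(optimizer="de", seed=0, tol=0.0, max_iter=1,
                        de={"F_range": [0.0, 0.0], "CR": 1.0})
        seen = []

        def spy(params):
            seen.append(params.copy())
            return sphere(params)

        res = de_search(cfg, spy)
        init = np.array(seen[:20])
        best0 = init[np.argmin([sphere(p) for p in init])]
        trials = np.array(seen[20:40])
        # CR = 1: trial == mutant == x_best in every gene
        for tr in trials:
            np.testing.assert_allclose(tr, best0, atol=1e-12)


class TestPSOKinematics:
    def test_zero_learning_rates_keep_velocity(self):
        V = np.array([[0.1, -0.2, 0.3]])
        X = np.zeros((1, 3))
        V2 = pso_velocity_update(V, X, X, X[0], inertia=1.0, c1=0.0, c2=0.0,
                                 r1=np.ones((1, 3)), r2=np.ones((1, 3)))
        np.testing.assert_array_equal(V2, V)

    def test_particle_at_global_best_with_zero_velocity_is_fixed(self):
        X = np.array([[0.4, 0.5, 0.6]])
        V = np.zeros((1, 3))
        V2 = pso_velocity_update(V, X, X.copy(), X[0].copy(), inertia=0.7,
                                 c1=2.0, c2=2.0,
                                 r1=np.full((1, 3), 0.3), r2=np.full((1, 3), 0.9))
        np.testing.assert_array_equal(V2, 0.0)
        np.testing.assert_array_equal(X + V2, X)


class TestRepair:
    def test_zero_lower_bound_nudged_for_trainable_params(self):
        lower = np.array([0.0, 0.0, 0.0])
        upper = np.array([10000.0, 2.0, 1e-4])
        x = _unit_to_params(np.array([0.0, 0.0, 0.0]), lower, upper)
        assert x[0] == pytest.approx(1e-6 * 10000.0)
        assert x[1] == pytest.approx(1e-6 * 2.0)
        assert x[2] == 0.0  # epsilon = 0 is a valid training value

    def test_out_of_box_clipped(self):
        lower = np.zeros(3)
        upper = np.array([1.0, 1.0, 1.0])
        x = _unit_to_params(np.array([1.7, -0.3, 0.5]), lower, upper)
        assert x[0] == 1.0 and x[2] == 0.5
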