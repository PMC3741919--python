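"""Fitness function and the three hyperparameter searchers (GA, DE, PSO).

All searchers minimize the same objective — the mean absolute percentage
error of the in-sample reconstruction,

    f = 100/n * sum_i |a_i - p_i| / a_i   [%]

over a bounded 3-D box of (C, sigma2, epsilon). Internally each searcher
works on the unit cube and maps candidates to physical bounds before
evaluation, so the wildly different parameter scales (C up to 1e4,
epsilon down to 1e-4) do not distort the search geometry. The shared
termination rule is: at most ``max_iter`` generations, or best fitness at
or below the absolute tolerance (default 0.001%).

A searcher accepts any evaluator ``f(params: ndarray[3]) -> float``; the
default SVR-based evaluator is :func:`evaluate_candidate`, but surrogate
functions plug in the same way (used heavily by the tests).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .data import Hyperparameters, RunConfig, SearchResult, get_logger, log_record
from .svr import rbf_gram, solve_dual, svr_predict, svr_train

__all__ = [
    "WORST_FITNESS",
    "fitness",
    "evaluate_candidate",
    "ga_search",
    "de_search",
    "pso_search",
    "search",
]

WORST_FITNESS = float("inf")

Evaluator = Callable[[np.ndarray], float]

_logger = get_logger("invecg.optimizers")


def fitness(actual: np.ndarray, predicted: np.ndarray, zero_guard: float = 1e-6) -> float:
    """Mean absolute percentage error, in percent.

    Division by near-zero actual values is rejected outright: targets
    scaled per time instant contain exact zeros, so callers should pass
    offset targets (a + c, p + c) — the pipeline does this with c = 1.
    """
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    if np.any(np.abs(a) < zero_guard):
        raise ValueError(
            "fitness is undefined for near-zero actual values; "
            "use scaled targets with an additive offset"
        )
    return float(np.mean(np.abs(a - p) / np.abs(a)) * 100.0)


def evaluate_candidate(
    hp: Hyperparameters,
    features: np.ndarray,
    targets: np.ndarray,
    fitness_offset: float = 1.0,
    svr_tol: float = 1e-5,
    svr_max_iter: int = 50_000,
) -> float:
    """Train an SVR with ``hp`` and return its in-sample fitness (%).

    The candidate is scored on the training set itself (the protocol the
    searchers assume). Degenerate hyperparameters (C or sigma2 at zero
    after repair) yield the worst-fitness sentinel instead of an error.
    """
    if hp.C <= 0 or hp.sigma2 <= 0:
        log_record(_logger, "degenerate_candidate", C=hp.C, sigma2=hp.sigma2)
        return WORST_FITNESS
    model = svr_train(features, targets, hp.C, hp.sigma2, hp.epsilon,
                      tol=svr_tol, max_iter=svr_max_iter)
    pred = svr_predict(model, features)
    return fitness(np.asarray(targets, float) + fitness_offset, pred + fitness_offset)


def make_svr_evaluator(
    features: np.ndarray,
    targets: np.ndarray,
    fitness_offset: float = 1.0,
    svr_tol: float = 1e-5,
    svr_max_iter: int = 5_000,
    cv_folds: int = 0,
) -> Evaluator:
    """Fast SVR evaluator over a fixed feature matrix.

    Precomputes the squared-distance matrix once; each candidate then only
    exponentiates it at its own bandwidth before the dual solve. All
    candidates across all nodes share the same features, so this is the
    pipeline's inner loop.

    With ``cv_folds = 0`` (default) the candidate is scored on its own
    training residuals, the protocol the searchers assume. ``cv_folds >= 2``
    switches to strided k-fold cross-validation: each fold is held out,
    the model is trained on the rest, and the pooled held-out predictions
    are scored. In-sample scoring systematically rewards vanishing kernel
    bandwidths (any interpolator looks perfect on its own training set);
    cross-validation penalizes them, at k times the cost per candidate.
    """
    from scipy.spatial.distance import cdist

    F = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.asarray(targets, dtype=float).ravel()
    n = t.shape[0]
    D2 = cdist(F, F, "sqeuclidean")
    off = float(fitness_offset)
    if cv_folds:
        if not 2 <= cv_folds <= n:
            raise ValueError(f"cv_folds must be in [2, {n}], got {cv_folds}")
        # strided folds keep every fold spread across the time axis
        fold_of = np.arange(n) % cv_folds

    def _eval(params: np.ndarray) -> float:
        C, s2, eps = float(params[0]), float(params[1]), float(params[2])
        if C <= 0 or s2 <= 0:
            return WORST_FITNESS
        K = np.exp(-D2 / (2.0 * s2))
        if not cv_folds:
            beta, b, _ = solve_dual(K, t, C, eps, tol=svr_tol, max_iter=svr_max_iter)
            pred = K @ beta + b
            return fitness(t + off, pred + off)
        pred = np.empty(n)
        for f in range(cv_folds):
            held = fold_of == f
            idx = np.flatnonzero(~held)
            Kf = np.ascontiguousarray(K[np.ix_(idx, idx)])
            beta, b, _ = solve_dual(Kf, t[idx], C, eps, tol=svr_tol,
                                    max_iter=svr_max_iter)
            pred[held] = K[np.ix_(held, idx)] @ beta + b
        return fitness(t + off, pred + off)

    return _eval


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------


def _unit_to_params(u: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Map a unit-cube point to physical bounds, nudging C and sigma2 off
    a zero lower bound (training degenerates at C = 0 or sigma2 = 0)."""
    x = lower + np.clip(u, 0.0, 1.0) * (upper - lower)
    for k in (0, 1):  # C, sigma2
        floor = lower[k] + 1e-6 * (upper[k] - lower[k])
        if x[k] <= lower[k] and lower[k] <= 0:
            x[k] = floor
    return x


def _evaluate_unit(u: np.ndarray, evaluator: Evaluator,
                   lower: np.ndarray, upper: np.ndarray) -> float:
    val = evaluator(_unit_to_params(u, lower, upper))
    return float(val) if np.isfinite(val) else WORST_FITNESS


def _result(best_u, best_f, trajectory, evaluations, lower, upper) -> SearchResult:
    p = _unit_to_params(best_u, lower, upper)
    return SearchResult(
        best=Hyperparameters(C=p[0], sigma2=p[1], epsilon=p[2]),
        best_fitness=float(best_f),
        trajectory=np.asarray(trajectory, dtype=float),
        generations=len(trajectory),
        evaluations=evaluations,
    )


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def _ga_decode(chrom: np.ndarray, bits: int, dim: int) -> np.ndarray:
    """Linear decode of a bitstring chromosome to the unit cube: all-zero
    bits -> 0 (lower bounds), all-one bits -> 1 (upper bounds)."""
    weights = 2.0 ** np.arange(bits - 1, -1, -1)
    denom = 2.0 ** bits - 1.0
    out = np.empty(dim)
    for k in range(dim):
        out[k] = chrom[k * bits:(k + 1) * bits] @ weights / denom
    return out


def _sus_select(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: n equally spaced pointers over the
    cumulative weight wheel."""
    total = weights.sum()
    if total <= 0:
        return rng.integers(0, weights.size, size=n)
    pointers = (rng.random() + np.arange(n)) / n * total
    return np.searchsorted(np.cumsum(weights), pointers)


def ga_search(config: RunConfig, evaluator: Evaluator,
              rng: np.random.Generator | None = None) -> SearchResult:
    """Binary-encoded GA: 20 bits per parameter, stochastic universal
    sampling with a 0.9 generation gap (elitism fills the rest), two-point
    crossover at rate 0.8, per-bit mutation at rate 0.05.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lower, upper = config.bounds.lower, config.bounds.upper
    NP, dim = config.population, 3
    bits = int(config.ga["bits_per_param"])
    gap = float(config.ga["selection_gap"])
    p_cx = float(config.ga["crossover_rate"])
    p_mut = float(config.ga["mutation_rate"])
    nbits = bits * dim

    pop = rng.integers(0, 2, size=(NP, nbits)).astype(np.int8)
    fits = np.array([
        _evaluate_unit(_ga_decode(c, bits, dim), evaluator, lower, upper) for c in pop
    ])
    evaluations = NP
    if not np.isfinite(fits).any():
        raise RuntimeError("GA: evaluator failed on every candidate of the initial population")
    best_i = int(np.argmin(fits))
    best_chrom = pop[best_i].copy()
    best_f = float(fits[best_i])
    trajectory = [best_f]
    log_record(_logger, "ga_generation", gen=1, best=best_f)

    gens = 1
    while gens <= config.max_iter and best_f > config.tol:
        n_off = int(round(gap * NP))
        n_elite = NP - n_off
        finite = np.isfinite(fits)
        capped = np.where(finite, fits, np.nanmax(fits[finite]) if finite.any() else 0.0)
        spread = capped.max() - capped.min()
        weights = (capped.max() - capped) + max(spread, 1.0) * 1e-3
        weights[~finite] = 0.0
        parents = pop[_sus_select(weights, n_off, rng)].copy()
        rng.shuffle(parents, axis=0)
        # two-point crossover on adjacent pairs
        for a in range(0, n_off - 1, 2):
            if rng.random() < p_cx:
                c1, c2 = sorted(rng.choice(np.arange(1, nbits), size=2, replace=False))
                tmp = parents[a, c1:c2].copy()
                parents[a, c1:c2] = parents[a + 1, c1:c2]
                parents[a + 1, c1:c2] = tmp
        flip = rng.random(parents.shape) < p_mut
        parents[flip] ^= 1
        off_fits = np.array([
            _evaluate_unit(_ga_decode(c, bits, dim), evaluator, lower, upper)
            for c in parents
        ])
        evaluations += n_off
        if not np.isfinite(off_fits).any() and n_elite == 0:
            raise RuntimeError("GA: evaluator failed on every candidate of a generation")
        elite_idx = np.argsort(fits, kind="stable")[:n_elite]
        pop = np.concatenate([pop[elite_idx], parents])
        fits = np.concatenate([fits[elite_idx], off_fits])
        gi = int(np.argmin(fits))
        if fits[gi] < best_f:
            best_f = float(fits[gi])
            best_chrom = pop[gi].copy()
        gens += 1
        trajectory.append(best_f)
        log_record(_logger, "ga_generation", gen=gens, best=best_f)

    best_u = _ga_decode(best_chrom, bits, dim)
    return _result(best_u, best_f, trajectory, evaluations, lower, upper)


# ---------------------------------------------------------------------------
# Differential evolution (DE/best/2/bin)
# ---------------------------------------------------------------------------


def de_search(config: RunConfig, evaluator: Evaluator,
              rng: np.random.Generator | None = None) -> SearchResult:
    """DE/best/2/bin: mutation around the current best with two scaled
    difference vectors, binomial crossover guaranteeing at least one mutant
    gene, greedy selection.

    The mutation factor F is drawn once per run uniformly from the
    configured range (default [0.5, 1]); CR defaults to 0.9.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lower, upper = config.bounds.lower, config.bounds.upper
    NP, dim = config.population, 3
    if NP < 6:
        raise ValueError("DE needs population >= 6 to draw 4 distinct partners plus i")
    f_lo, f_hi = config.de["F_range"]
    F = float(rng.uniform(f_lo, f_hi))
    CR = float(config.de["CR"])

    pop = rng.random((NP, dim))
    fits = np.array([_evaluate_unit(u, evaluator, lower, upper) for u in pop])
    evaluations = NP
    bi = int(np.argmin(fits))
    x_best = pop[bi].copy()
    best_f = float(fits[bi])
    trajectory = [best_f]
    log_record(_logger, "de_generation", gen=1, best=best_f, F=F, CR=CR)

    gens = 1
    while gens <= config.max_iter and best_f > config.tol:
        trials = np.empty_like(pop)
        for i in range(NP):
            choices = np.delete(np.arange(NP), i)
            r1, r2, r3, r4 = rng.choice(choices, size=4, replace=False)
            v = x_best + F * ((pop[r1] - pop[r2]) + (pop[r3] - pop[r4]))
            v = np.clip(v, 0.0, 1.0)
            jr = int(rng.integers(dim))
            mask = rng.random(dim) <= CR
            mask[jr] = True
            trials[i] = np.where(mask, v, pop[i])
        t_fits = np.array([_evaluate_unit(u, evaluator, lower, upper) for u in trials])
        evaluations += NP
        # greedy per-individual selection keeps the population evolving
        improved = t_fits <= fits
        pop[improved] = trials[improved]
        fits[improved] = t_fits[improved]
        ui = int(np.argmin(t_fits))
        if t_fits[ui] <= best_f:
            best_f = float(t_fits[ui])
            x_best = trials[ui].copy()
        gens += 1
        trajectory.append(best_f)
        log_record(_logger, "de_generation", gen=gens, best=best_f)

    return _result(x_best, best_f, trajectory, evaluations, lower, upper)


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------


def pso_velocity_update(
    V: np.ndarray,
    X: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    inertia: float,
    c1: float,
    c2: float,
    r1: np.ndarray,
    r2: np.ndarray,
) -> np.ndarray:
    """One velocity update: V' = w V + c1 r1 (p_i - X) + c2 r2 (p_g - X)."""
    return inertia * V + c1 * r1 * (pbest - X) + c2 * r2 * (gbest - X)


def pso_search(config: RunConfig, evaluator: Evaluator,
               rng: np.random.Generator | None = None) -> SearchResult:
    """Global-best PSO with linearly decreasing inertia (0.9 -> 0.4 by
    default), c1 = c2 = 2, unit time step, velocities clamped to +/- half
    the search range per dimension, positions clipped to the box."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lower, upper = config.bounds.lower, config.bounds.upper
    NP, dim = config.population, 3
    c = config.pso
    w0, w1 = float(c["inertia_start"]), float(c["inertia_end"])
    c1, c2, dt = float(c["c1"]), float(c["c2"]), float(c["dt"])
    vmax = float(c["vmax_frac"])  # unit cube: range is 1 per dimension

    X = rng.random((NP, dim))
    V = rng.uniform(-vmax, vmax, size=(NP, dim))
    fits = np.array([_evaluate_unit(x, evaluator, lower, upper) for x in X])
    evaluations = NP
    pbest = X.copy()
    pbest_f = fits.copy()
    gi = int(np.argmin(fits))
    gbest = X[gi].copy()
    gbest_f = float(fits[gi])
    trajectory = [gbest_f]
    log_record(_logger, "pso_generation", gen=1, best=gbest_f)

    gens = 1
    n_steps = config.max_iter
    while gens <= config.max_iter and gbest_f > config.tol:
        k = gens - 1
        w = w0 + (w1 - w0) * (k / max(n_steps - 1, 1))
        r1 = rng.random((NP, dim))
        r2 = rng.random((NP, dim))
        V = pso_velocity_update(V, X, pbest, gbest, w, c1, c2, r1, r2)
        V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V * dt, 0.0, 1.0)
        fits = np.array([_evaluate_unit(x, evaluator, lower, upper) for x in X])
        evaluations += NP
        better = fits < pbest_f
        pbest[better] = X[better]
        pbest_f[better] = fits[better]
        gi = int(np.argmin(pbest_f))
        if pbest_f[gi] < gbest_f:
            gbest_f = float(pbest_f[gi])
            gbest = pbest[gi].copy()
        gens += 1
        trajectory.append(gbest_f)
        log_record(_logger, "pso_generation", gen=gens, best=gbest_f)

    return _result(gbest, gbest_f, trajectory, evaluations, lower, upper)


_SEARCHERS = {"ga": ga_search, "de": de_search, "pso": pso_search}


def search(config: RunConfig, evaluator: Evaluator,
           rng: np.random.Generator | None = None) -> SearchResult:
    """Dispatch to the configured searcher."""
    return _SEARCHERS[config.optimizer](config, evaluator, rng)
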