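"""Epsilon-insensitive support vector regression with an RBF kernel.

Training solves the standard dual

    min_{a, a*}  1/2 (a - a*)' K (a - a*) - y'(a - a*) + eps * sum(a + a*)
    s.t.         sum(a - a*) = 0,   0 <= a_i, a*_i <= C

by sequential minimal optimization over the 2N stacked variables with the
maximal-violating-pair working-set rule and a deterministic lowest-index
tie-break. Prediction is the kernel expansion
f(x) = sum_i beta_i K(x_i, x) + b with beta = a - a*.

The two-coefficient inner loop is jitted with numba: the per-node
hyperparameter searches of the full pipeline train tens of thousands of
small SVR models, so the solver core must be cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

__all__ = [
    "SVRModel",
    "rbf_kernel",
    "rbf_gram",
    "svr_train",
    "svr_predict",
    "solve_dual",
    "dual_objective",
]


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma2: float) -> float:
    """exp(-||x - y||^2 / (2 sigma2)); symmetric, 1 iff x == y."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma2)))


def rbf_gram(X: np.ndarray, Y: np.ndarray, sigma2: float) -> np.ndarray:
    """RBF kernel matrix between the rows of X and Y."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    return np.exp(-cdist(np.atleast_2d(X), np.atleast_2d(Y), "sqeuclidean") / (2.0 * sigma2))


@njit(cache=True)
def _smo(K, y, C, eps, tol, max_iter):  # pragma: no cover - exercised via solve_dual
    """SMO over alpha = [a; a*] (length 2n). Returns (alpha, b, iters, gap).

    Working-set selection: i is the maximal-violating index of the "up"
    set; j minimizes the second-order objective decrease among "down"
    indices that still violate against i (the selection rule of modern
    SMO solvers). Ties break to the lowest index via strict comparisons.
    """
    n = y.shape[0]
    m2 = 2 * n
    alpha = np.zeros(m2)
    g = np.empty(m2)
    for i in range(n):
        g[i] = eps - y[i]
        g[n + i] = eps + y[i]
    it = 0
    gap = np.inf
    while it < max_iter:
        # i: maximal -z*g over the "up" set
        i_sel = -1
        m_val = -np.inf
        M_val = np.inf
        for s in range(m2):
            z = 1.0 if s < n else -1.0
            a = alpha[s]
            v = -z * g[s]
            if ((z > 0.0 and a < C) or (z < 0.0 and a > 0.0)) and v > m_val:
                m_val = v
                i_sel = s
            if ((z > 0.0 and a > 0.0) or (z < 0.0 and a < C)) and v < M_val:
                M_val = v
        gap = m_val - M_val
        if i_sel < 0 or gap < tol:
            break
        bi = i_sel % n
        zi = 1.0 if i_sel < n else -1.0
        # j: best second-order decrease among violating "down" indices
        j_sel = -1
        best_dec = 0.0
        for s in range(m2):
            z = 1.0 if s < n else -1.0
            a = alpha[s]
            if not ((z > 0.0 and a > 0.0) or (z < 0.0 and a < C)):
                continue
            diff = m_val - (-z * g[s])
            if diff <= 0.0:
                continue
            bs = s % n
            quad = K[bi, bi] + K[bs, bs] - 2.0 * zi * z * K[bi, bs]
            if quad <= 1e-12:
                quad = 1e-12
            dec = diff * diff / quad
            if dec > best_dec:
                best_dec = dec
                j_sel = s
        if j_sel < 0:
            break
        bj = j_sel % n
        zj = 1.0 if j_sel < n else -1.0
        quad = K[bi, bi] + K[bj, bj] - 2.0 * zi * zj * K[bi, bj]
        if quad <= 1e-12:
            quad = 1e-12
        lam = (m_val - (-zj * g[j_sel])) / quad
        # box caps along the feasible direction (delta_i = zi*lam, delta_j = -zj*lam)
        cap_i = (C - alpha[i_sel]) if zi > 0.0 else alpha[i_sel]
        cap_j = alpha[j_sel] if zj > 0.0 else (C - alpha[j_sel])
        if lam > cap_i:
            lam = cap_i
        if lam > cap_j:
            lam = cap_j
        alpha[i_sel] += zi * lam
        alpha[j_sel] -= zj * lam
        di = zi * lam
        dj = -zj * lam
        for s in range(n):
            d = zi * K[s, bi] * di + zj * K[s, bj] * dj
            g[s] += d
            g[n + s] -= d
        it += 1
    # bias: average KKT-implied value over free vectors, else interval midpoint
    b_sum = 0.0
    n_free = 0
    for s in range(m2):
        a = alpha[s]
        if 0.0 < a < C:
            z = 1.0 if s < n else -1.0
            b_sum += -z * g[s]
            n_free += 1
    if n_free > 0:
        b = b_sum / n_free
    else:
        m_val = -np.inf
        M_val = np.inf
        for s in range(m2):
            z = 1.0 if s < n else -1.0
            a = alpha[s]
            v = -z * g[s]
            if ((z > 0.0 and a < C) or (z < 0.0 and a > 0.0)) and v > m_val:
                m_val = v
            if ((z > 0.0 and a > 0.0) or (z < 0.0 and a < C)) and v < M_val:
                M_val = v
        if np.isfinite(m_val) and np.isfinite(M_val):
            b = 0.5 * (m_val + M_val)
        else:
            b = 0.0
    return alpha, b, it, gap


def solve_dual(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    eps: float,
    tol: float = 1e-3,
    max_iter: int = 200_000,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Solve the dual on a precomputed Gram matrix.

    Returns ``(beta, b, alpha)`` where ``beta = alpha[:n] - alpha[n:]``.
    This is the fast path used by the pipeline, which reuses one squared-
    distance matrix across all kernel bandwidths.
    """
    K = np.ascontiguousarray(K, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    alpha, b, _, _ = _smo(K, y, float(C), float(eps), float(tol), int(max_iter))
    n = y.shape[0]
    beta = alpha[:n] - alpha[n:]
    beta[np.abs(beta) < 1e-12] = 0.0
    return beta, float(b), alpha


def dual_objective(K: np.ndarray, y: np.ndarray, eps: float, alpha: np.ndarray) -> float:
    """Dual objective 1/2 b'Kb - y'b + eps * sum(alpha) at a 2n-vector alpha."""
    n = y.shape[0]
    beta = alpha[:n] - alpha[n:]
    return float(0.5 * beta @ K @ beta - y @ beta + eps * alpha.sum())


@dataclass(frozen=True)
class SVRModel:
    """Trained epsilon-SVR: support vectors, dual coefficient differences
    beta_i = a_i - a*_i, bias b, and the training hyperparameters."""

    support_vectors: np.ndarray
    beta: np.ndarray
    b: float
    sigma2: float
    C: float
    epsilon: float
    dual_obj: float
    n_iter: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "beta": self.beta.tolist(),
            "b": self.b,
            "sigma2": self.sigma2,
            "C": self.C,
            "epsilon": self.epsilon,
            "dual_obj": self.dual_obj,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        return cls(
            np.asarray(d["support_vectors"], dtype=float),
            np.asarray(d["beta"], dtype=float),
            float(d["b"]),
            float(d["sigma2"]),
            float(d["C"]),
            float(d["epsilon"]),
            float(d["dual_obj"]),
            int(d["n_iter"]),
            bool(d["converged"]),
        )


def svr_train(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    sigma2: float,
    epsilon: float,
    tol: float = 1e-3,
    max_iter: int = 200_000,
) -> SVRModel:
    """Train an epsilon-SVR with RBF bandwidth ``sigma2``.

    The returned coefficients satisfy sum(beta) = 0 and |beta_i| <= C;
    support vectors are exactly the training points with nonzero beta.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} targets")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    K = rbf_gram(X, X, sigma2)
    K_c = np.ascontiguousarray(K)
    alpha, b, it, gap = _smo(K_c, np.ascontiguousarray(y), float(C), float(epsilon),
                             float(tol), int(max_iter))
    n = y.shape[0]
    beta = alpha[:n] - alpha[n:]
    beta[np.abs(beta) < 1e-12] = 0.0
    sv = beta != 0.0
    obj = dual_objective(K, y, epsilon, alpha)
    return SVRModel(
        support_vectors=X[sv].copy(),
        beta=beta[sv].copy(),
        b=float(b),
        sigma2=float(sigma2),
        C=float(C),
        epsilon=float(epsilon),
        dual_obj=obj,
        n_iter=it,
        converged=bool(gap < tol),
    )


def svr_predict(model: SVRModel, X_new: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = sum_i beta_i K(x_i, x) + b at the rows of X_new."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if model.support_vectors.shape[0] == 0:
        return np.full(X_new.shape[0], model.b)
    if X_new.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"expected {model.support_vectors.shape[1]} features, got {X_new.shape[1]}"
        )
    K = rbf_gram(X_new, model.support_vectors, model.sigma2)
    return K @ model.beta + model.b
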