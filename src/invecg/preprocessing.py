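"""Row-wise min-max scaling and kernel-PCA feature extraction.

Scaling normalizes each time instant's potential pattern across leads (or
nodes) to [0, 1]: phi' = (phi - phi_min) / (phi_max - phi_min), with the
extremes taken per row. KPCA then reduces the BSP lead dimension by
principal component analysis of a centered RBF (or, for validation,
linear) kernel matrix, with out-of-sample projection for test rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ScalingParams",
    "KPCAModel",
    "scale_rows",
    "unscale_rows",
    "kpca_fit",
    "kpca_transform",
    "median_squared_distance",
]


@dataclass(frozen=True)
class ScalingParams:
    """Per-row extremes recorded by :func:`scale_rows`.

    ``degenerate`` flags rows with max == min, which scale to all zeros and
    unscale back to the stored constant.
    """

    mins: np.ndarray
    maxs: np.ndarray
    degenerate: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.mins.shape[0]

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "degenerate": self.degenerate.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            np.asarray(d["mins"], dtype=float),
            np.asarray(d["maxs"], dtype=float),
            np.asarray(d["degenerate"], dtype=bool),
        )


def scale_rows(matrix: np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    """Scale each row to [0, 1] by its own extremes.

    Degenerate (constant) rows map to all zeros and are flagged so that
    :func:`unscale_rows` can restore the constant.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    mins = matrix.min(axis=1)
    maxs = matrix.max(axis=1)
    span = maxs - mins
    degenerate = span == 0
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (matrix - mins[:, None]) / safe_span[:, None]
    scaled[degenerate] = 0.0
    return scaled, ScalingParams(mins, maxs, degenerate)


def unscale_rows(scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Exact inverse of :func:`scale_rows` (constant rows restore the
    stored constant)."""
    scaled = np.atleast_2d(np.asarray(scaled, dtype=float))
    if scaled.shape[0] != params.n_rows:
        raise ValueError(
            f"matrix has {scaled.shape[0]} rows but params describe {params.n_rows}"
        )
    span = np.where(params.degenerate, 0.0, params.maxs - params.mins)
    out = scaled * span[:, None] + params.mins[:, None]
    out[params.degenerate] = params.mins[params.degenerate, None]
    return out


# ---------------------------------------------------------------------------
# Kernel PCA
# ---------------------------------------------------------------------------


def median_squared_distance(X: np.ndarray) -> float:
    """Median of the squared pairwise distances — the bandwidth heuristic
    used when no KPCA bandwidth is configured."""
    d2 = cdist(X, X, "sqeuclidean")
    iu = np.triu_indices_from(d2, k=1)
    vals = d2[iu]
    med = float(np.median(vals)) if vals.size else 1.0
    return med if med > 0 else 1.0


def _kernel(X: np.ndarray, Y: np.ndarray, kind: str, bandwidth: float) -> np.ndarray:
    if kind == "rbf":
        return np.exp(-cdist(X, Y, "sqeuclidean") / (2.0 * bandwidth))
    if kind == "linear":
        return X @ Y.T
    raise ValueError(f"unknown kernel {kind!r}")


@dataclass(frozen=True)
class KPCAModel:
    """Fitted kernel-PCA projector.

    ``alphas`` holds the centered-kernel eigenvectors scaled by the inverse
    square roots of their eigenvalues, so training scores are
    ``K_centered @ alphas`` and have per-component variance
    ``eigenvalue / n_samples``. ``row_means``/``grand_mean`` reproduce the
    training centering for new points.
    """

    X_train: np.ndarray
    kernel: str
    bandwidth: float
    alphas: np.ndarray
    eigenvalues: np.ndarray
    row_means: np.ndarray
    grand_mean: float
    d: int

    def to_dict(self) -> dict:
        return {
            "X_train": self.X_train.tolist(),
            "kernel": self.kernel,
            "bandwidth": self.bandwidth,
            "alphas": self.alphas.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "row_means": self.row_means.tolist(),
            "grand_mean": self.grand_mean,
            "d": self.d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KPCAModel":
        return cls(
            np.asarray(d["X_train"], dtype=float),
            d["kernel"],
            float(d["bandwidth"]),
            np.asarray(d["alphas"], dtype=float),
            np.asarray(d["eigenvalues"], dtype=float),
            np.asarray(d["row_means"], dtype=float),
            float(d["grand_mean"]),
            int(d["d"]),
        )


def kpca_fit(
    X: np.ndarray,
    d: int,
    bandwidth: float | None = None,
    kernel: str = "rbf",
) -> KPCAModel:
    """Fit KPCA on training vectors ``X`` (samples x leads).

    The top-``d`` eigenpairs of the double-centered kernel matrix are
    retained; eigenvector signs are fixed by making each vector's
    largest-magnitude entry positive so results are deterministic across
    linear-algebra backends.

    Raises
    ------
    ValueError
        If fewer than ``d`` positive eigenvalues exist (the achievable rank
        is reported).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if d < 1 or d > n:
        raise ValueError(f"d must be in [1, {n}], got {d}")
    if kernel == "rbf":
        if bandwidth is None:
            bandwidth = median_squared_distance(X)
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
    else:
        bandwidth = float(bandwidth or 1.0)
    K = _kernel(X, X, kernel, bandwidth)
    row_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - row_means[None, :] - row_means[:, None] + grand
    evals, evecs = np.linalg.eigh(Kc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(evals[0], 0.0) * 1e-12
    rank = int(positive.sum())
    if rank < d:
        raise ValueError(
            f"only {rank} positive eigenvalues available, cannot retain d={d} components"
        )
    evals, evecs = evals[:d], evecs[:, :d]
    # deterministic sign: largest-magnitude loading positive
    for j in range(d):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    alphas = evecs / np.sqrt(evals)[None, :]
    return KPCAModel(X, kernel, float(bandwidth), alphas, evals, row_means, grand, d)


def kpca_transform(model: KPCAModel, X_new: np.ndarray) -> np.ndarray:
    """Out-of-sample projection onto the fitted components.

    New kernel rows are centered against the stored training statistics;
    transforming the training matrix itself reproduces the training scores.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"expected {model.X_train.shape[1]} columns, got {X_new.shape[1]}"
        )
    Kn = _kernel(X_new, model.X_train, model.kernel, model.bandwidth)
    Kn_c = (
        Kn
        - Kn.mean(axis=1, keepdims=True)
        - model.row_means[None, :]
        + model.grand_mean
    )
    return Kn_c @ model.alphas
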