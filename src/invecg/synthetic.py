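"""Synthetic forward-model data: action-potential-like TMP time courses
pushed through a linear, ill-conditioned transfer matrix plus noise.

This stands in for a physiological heart-torso simulation. Each cardiac
node's transmembrane potential is a smooth depolarization/repolarization
pulse (product of two sigmoids between a resting and a plateau level);
body-surface potentials are a linear mix of all node courses through a
transfer matrix with an exponentially decaying singular spectrum, which
reproduces the smoothing/ill-conditioning that makes the inverse problem
hard. Gaussian noise is added at a configured signal-to-noise ratio.

The default dimensions (T = 120 time steps, L = 40 leads, N = 50 nodes,
SNR 30 dB) are a desk-scale configuration on which a full three-optimizer
comparison runs in minutes; ``PAPER_SCALE`` (T = 358, L = 412, N = 478)
reproduces the full-scale matrix shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PotentialDataset

__all__ = [
    "APWaveformParams",
    "ForwardModel",
    "generate_tmp",
    "generate_forward_model",
    "generate_dataset",
    "default_waveforms",
    "PAPER_SCALE",
    "DESK_SCALE",
]

DESK_SCALE = {"T": 120, "L": 40, "N": 50}
PAPER_SCALE = {"T": 358, "L": 412, "N": 478}


@dataclass(frozen=True)
class APWaveformParams:
    """Shape of one node's action-potential-like time course.

    ``activation_ms`` is the upstroke midpoint tau; the course is

        resting + (plateau - resting)
                * sigmoid((t - tau) / upstroke_ms)
                * sigmoid((tau + plateau_ms - t) / repol_ms)

    so ``upstroke_ms`` and ``repol_ms`` are the rise/fall widths and
    ``plateau_ms`` the depolarized duration. Defaults follow textbook
    ventricular values: resting -85 mV, plateau +15 mV.
    """

    activation_ms: float
    resting_mv: float = -85.0
    plateau_mv: float = 15.0
    upstroke_ms: float = 2.0
    plateau_ms: float = 40.0
    repol_ms: float = 12.0

    def __post_init__(self) -> None:
        if self.upstroke_ms <= 0 or self.repol_ms <= 0:
            raise ValueError("upstroke_ms and repol_ms must be > 0")
        if self.plateau_ms < 0:
            raise ValueError("plateau_ms must be >= 0")


@dataclass(frozen=True)
class ForwardModel:
    """Linear transfer matrix A (leads x nodes) with controlled conditioning.

    Singular values decay as exp(-decay * k); ``condition_number`` is thus
    about exp(decay * (rank - 1)).
    """

    A: np.ndarray
    decay: float
    snr_db: float | None

    @property
    def condition_number(self) -> float:
        s = np.linalg.svd(self.A, compute_uv=False)
        return float(s[0] / s[-1])


def generate_tmp(params: list[APWaveformParams], times: np.ndarray) -> np.ndarray:
    """TMP matrix (T x N): one smooth pulse per node.

    Raises if any activation time lies outside the simulated interval.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 time samples")
    t0, t1 = times[0], times[-1]
    cols = []
    for p in params:
        if not (t0 <= p.activation_ms <= t1):
            raise ValueError(
                f"activation time {p.activation_ms} ms outside interval [{t0}, {t1}]"
            )
        up = 1.0 / (1.0 + np.exp(-(times - p.activation_ms) / p.upstroke_ms))
        down = 1.0 / (1.0 + np.exp(-((p.activation_ms + p.plateau_ms) - times) / p.repol_ms))
        cols.append(p.resting_mv + (p.plateau_mv - p.resting_mv) * up * down)
    return np.column_stack(cols)


def generate_forward_model(
    L: int, N: int, decay: float, seed: int, snr_db: float | None = None
) -> ForwardModel:
    """Transfer matrix from random orthogonal factors and singular values
    sigma_k = exp(-decay * k), k = 0..min(L,N)-1. Deterministic per seed."""
    if L < 2 or N < 2:
        raise ValueError("L and N must be >= 2")
    if decay < 0:
        raise ValueError("decay must be >= 0")
    rng = np.random.default_rng(seed)
    r = min(L, N)
    U, _ = np.linalg.qr(rng.standard_normal((L, r)))
    V, _ = np.linalg.qr(rng.standard_normal((N, r)))
    s = np.exp(-decay * np.arange(r))
    return ForwardModel(A=(U * s) @ V.T, decay=float(decay), snr_db=snr_db)


def default_waveforms(
    N: int, times: np.ndarray, rng: np.random.Generator
) -> list[APWaveformParams]:
    """Per-node waveform parameters emulating a normal excitation sequence.

    The simulated window starts at the first breakthrough, so activation
    times spread from the window origin across the first 40% of the span
    (linear gradient across node index plus a small jitter); pulse widths
    scale with the window so every node depolarizes and repolarizes inside
    it.
    """
    times = np.asarray(times, dtype=float)
    span = times[-1] - times[0]
    base = times[0] + np.linspace(0.0, 0.4 * span, N)
    jitter = rng.uniform(0.0, 0.02 * span, size=N)
    taus = np.minimum(base + jitter, times[-1])
    return [
        APWaveformParams(
            activation_ms=float(tau),
            plateau_ms=0.3 * span,
            repol_ms=0.1 * span,
            upstroke_ms=2.0,
        )
        for tau in taus
    ]


def generate_dataset(
    T: int = 120,
    L: int = 40,
    N: int = 50,
    snr_db: float | None = 30.0,
    decay: float = 0.15,
    seed: int = 0,
    waveforms: list[APWaveformParams] | None = None,
) -> PotentialDataset:
    """Generate a paired (BSP, TMP) dataset.

    Times are the integer grid 0..T-1 ms. BSP rows are ``tmp @ A.T`` plus
    Gaussian noise scaled so the matrix-wide signal-to-noise ratio equals
    ``snr_db`` (``None`` disables noise entirely). Pure function of its
    arguments plus the seed.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(T, dtype=float)
    if waveforms is None:
        waveforms = default_waveforms(N, times, rng)
    if len(waveforms) != N:
        raise ValueError(f"need {N} waveform parameter sets, got {len(waveforms)}")
    tmp = generate_tmp(waveforms, times)
    fwd = generate_forward_model(L, N, decay, seed=seed + 1, snr_db=snr_db)
    bsp = tmp @ fwd.A.T
    if snr_db is not None:
        signal_power = float(np.mean(bsp**2))
        noise_power = signal_power / (10.0 ** (snr_db / 10.0))
        bsp = bsp + rng.normal(0.0, np.sqrt(noise_power), size=bsp.shape)
    return PotentialDataset(bsp=bsp, tmp=tmp, times=times)
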