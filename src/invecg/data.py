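"""Core data types and delimited-text I/O for potential matrices.

The framework works on paired temporal potential matrices: body surface
potentials (BSP, time x leads) recorded on the torso and transmembrane
potentials (TMP, time x cardiac-surface nodes) on the heart, sharing one
time axis in milliseconds. Files are comma-delimited text with a single
header row and a leading ``time_ms`` column — human-inspectable and
lossless at 17 significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "PotentialDataset",
    "Hyperparameters",
    "HyperparameterBounds",
    "RunConfig",
    "SearchResult",
    "MatrixParseError",
    "read_potential_matrix",
    "write_potential_matrix",
    "split_dataset",
    "make_test_schedule",
    "get_logger",
    "log_record",
]

logger = logging.getLogger("invecg")


class MatrixParseError(ValueError):
    """Raised when a potential-matrix file is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PotentialDataset:
    """Paired BSP and TMP matrices over a shared, strictly increasing time axis.

    Parameters
    ----------
    bsp : ndarray, shape (T, L)
        Body surface potentials in millivolts, one row per time instant.
    tmp : ndarray, shape (T, N)
        Transmembrane potentials in millivolts on the cardiac surface nodes.
    times : ndarray, shape (T,)
        Time stamps in milliseconds, strictly increasing.
    """

    bsp: np.ndarray
    tmp: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        bsp = np.asarray(self.bsp, dtype=float)
        tmp = np.asarray(self.tmp, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if bsp.ndim != 2 or tmp.ndim != 2:
            raise ValueError("bsp and tmp must be 2-D matrices")
        if bsp.shape[0] != tmp.shape[0]:
            raise ValueError(
                f"bsp has {bsp.shape[0]} rows but tmp has {tmp.shape[0]}; "
                "they must share the time axis"
            )
        if times.ndim != 1 or times.shape[0] != bsp.shape[0]:
            raise ValueError("times must be 1-D with one entry per matrix row")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in (("bsp", bsp), ("tmp", tmp), ("times", times)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        object.__setattr__(self, "bsp", bsp)
        object.__setattr__(self, "tmp", tmp)
        object.__setattr__(self, "times", times)

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    @property
    def n_leads(self) -> int:
        return self.bsp.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.tmp.shape[1]

    def take(self, rows: np.ndarray) -> "PotentialDataset":
        """Row-subset the dataset, preserving order of ``rows``."""
        return PotentialDataset(self.bsp[rows], self.tmp[rows], self.times[rows])


@dataclass(frozen=True)
class Hyperparameters:
    """The SVR hyperparameter triple searched by every optimizer.

    ``C`` is the penalty weight on margin violations, ``sigma2`` the RBF
    kernel bandwidth sigma^2, and ``epsilon`` the half-width of the
    insensitive zone (in scaled-potential units).
    """

    C: float
    sigma2: float
    epsilon: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.C, self.sigma2, self.epsilon]).all():
            raise ValueError("hyperparameters must be finite")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def require_trainable(self) -> None:
        """Training needs strictly positive C and sigma2."""
        if self.C <= 0:
            raise ValueError(f"C must be > 0 for training, got {self.C}")
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0 for training, got {self.sigma2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.sigma2, self.epsilon], dtype=float)


@dataclass(frozen=True)
class HyperparameterBounds:
    """Search box for (C, sigma2, epsilon). Defaults are the standard ranges
    C in [0, 10000], sigma2 in [0, 2], epsilon in [0, 1e-4]."""

    C: tuple[float, float] = (0.0, 10000.0)
    sigma2: tuple[float, float] = (0.0, 2.0)
    epsilon: tuple[float, float] = (0.0, 1e-4)

    def __post_init__(self) -> None:
        for name in ("C", "sigma2", "epsilon"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"{name} bounds must be finite")
            if not lo < hi:
                raise ValueError(f"{name} bounds need lower < upper, got ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.C[0], self.sigma2[0], self.epsilon[0]], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.C[1], self.sigma2[1], self.epsilon[1]], dtype=float)


@dataclass
class RunConfig:
    """Configuration of one optimizer run and the surrounding pipeline.

    The defaults mirror the framework's standard protocol: population size
    20, at most 30 generations, absolute fitness tolerance 0.001 (%).
    Per-optimizer constants live in small nested dicts so they can be
    round-tripped through YAML unchanged.
    """

    optimizer: str = "pso"
    population: int = 20
    max_iter: int = 30
    tol: float = 0.001
    bounds: HyperparameterBounds = field(default_factory=HyperparameterBounds)
    kpca_dim: int = 20
    kpca_bandwidth: float | None = None  # None -> median heuristic
    seed: int = 0
    fitness_offset: float = 1.0
    cv_folds: int = 0  # 0 -> in-sample fitness (the faithful default)
    svr_tol: float = 1e-5
    svr_max_iter: int = 5000
    ga: dict = field(
        default_factory=lambda: {
            "bits_per_param": 20,
            "selection_gap": 0.9,
            "crossover_rate": 0.8,
            "mutation_rate": 0.05,
        }
    )
    de: dict = field(
        default_factory=lambda: {"F_range": [0.5, 1.0], "CR": 0.9}
    )
    pso: dict = field(
        default_factory=lambda: {
            "inertia_start": 0.9,
            "inertia_end": 0.4,
            "c1": 2.0,
            "c2": 2.0,
            "dt": 1.0,
            "vmax_frac": 0.5,
        }
    )

    def __post_init__(self) -> None:
        if self.optimizer not in ("ga", "de", "pso"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.population < 5:
            raise ValueError("population size must be >= 5")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if isinstance(self.bounds, dict):
            self.bounds = HyperparameterBounds(
                **{k: tuple(v) for k, v in self.bounds.items()}
            )

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["bounds"] = {
            "C": list(self.bounds.C),
            "sigma2": list(self.bounds.sigma2),
            "epsilon": list(self.bounds.epsilon),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one hyperparameter search.

    ``trajectory`` holds the best-so-far fitness (%) after each population
    evaluation, the initial population counting as generation 1; it is
    non-increasing by construction and its last entry equals
    ``best_fitness``.
    """

    best: Hyperparameters
    best_fitness: float
    trajectory: np.ndarray
    generations: int
    evaluations: int

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectory, dtype=float)
        object.__setattr__(self, "trajectory", traj)
        if traj.size and not np.all(np.diff(traj) <= 0):
            raise ValueError("trajectory must be non-increasing")
        if traj.size and traj[-1] != self.best_fitness:
            raise ValueError("best fitness must equal the last trajectory entry")


# ---------------------------------------------------------------------------
# Matrix file I/O
# ---------------------------------------------------------------------------


def read_potential_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited potential matrix.

    The file has one header row of column labels and a leading time-stamp
    column. Returns ``(matrix, times)`` with column order preserved.

    Raises
    ------
    MatrixParseError
        On a row with the wrong field count or a non-numeric cell, naming
        the offending 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    header = lines[0].split(",")
    n_fields = len(header)
    if n_fields < 2:
        raise MatrixParseError(f"{path}: header must have a time column and >= 1 lead")
    times: list[float] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(",")
        if len(fields) != n_fields:
            raise MatrixParseError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_fields}"
            )
        try:
            values = [float(f) for f in fields]
        except ValueError as exc:
            raise MatrixParseError(f"{path}: line {lineno}: {exc}") from None
        times.append(values[0])
        rows.append(values[1:])
    return np.asarray(rows, dtype=float), np.asarray(times, dtype=float)


def write_potential_matrix(
    matrix: np.ndarray,
    times: np.ndarray,
    path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    """Write a matrix readable by :func:`read_potential_matrix` at full
    (17 significant digit) precision."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    times = np.asarray(times, dtype=float)
    if matrix.shape[0] != times.shape[0]:
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but times has {times.shape[0]} entries"
        )
    if labels is None:
        labels = [f"c{j}" for j in range(matrix.shape[1])]
    if len(labels) != matrix.shape[1]:
        raise ValueError("one label per column required")
    with open(path, "w") as fh:
        fh.write("time_ms," + ",".join(labels) + "\n")
        for t, row in zip(times, matrix):
            fh.write(f"{t:.17g}," + ",".join(f"{v:.17g}" for v in row) + "\n")


def write_dataset(ds: PotentialDataset, bsp_path: str | Path, tmp_path: str | Path) -> None:
    write_potential_matrix(ds.bsp, ds.times, bsp_path,
                           labels=[f"lead{j}" for j in range(ds.n_leads)])
    write_potential_matrix(ds.tmp, ds.times, tmp_path,
                           labels=[f"node{j}" for j in range(ds.n_nodes)])


def read_dataset(bsp_path: str | Path, tmp_path: str | Path) -> PotentialDataset:
    bsp, t1 = read_potential_matrix(bsp_path)
    tmp, t2 = read_potential_matrix(tmp_path)
    if t1.shape != t2.shape or not np.array_equal(t1, t2):
        raise ValueError("BSP and TMP files disagree on the time axis")
    return PotentialDataset(bsp, tmp, t1)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


def make_test_schedule(start: float = 3.0, step: float = 6.0, stop: float = 357.0) -> np.ndarray:
    """Arithmetic test-time schedule, end-inclusive. The default (3, 9, ...,
    357 ms) selects 60 test instants out of a 0..357 ms grid."""
    n = int(np.floor((stop - start) / step)) + 1
    return start + step * np.arange(n)


def split_dataset(
    dataset: PotentialDataset, test_times: Iterable[float]
) -> tuple[PotentialDataset, PotentialDataset]:
    """Partition rows by time stamp: rows at ``test_times`` (original order)
    become the test set, all others the training set."""
    wanted = np.asarray(sorted(set(float(t) for t in test_times)), dtype=float)
    mask = np.isin(dataset.times, wanted)
    found = set(dataset.times[mask].tolist())
    missing = [t for t in wanted if t not in found]
    if missing:
        raise ValueError(f"test times not present in dataset: {missing}")
    return dataset.take(~mask), dataset.take(mask)


# ---------------------------------------------------------------------------
# Structured logging
# ---------------------------------------------------------------------------


def get_logger(name: str = "invecg") -> logging.Logger:
    return logging.getLogger(name)


def log_record(log: logging.Logger, event: str, **fields) -> None:
    """One structured line-delimited record: ``event key=value ...``."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    log.info("%s %s", event, payload)
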