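"""End-to-end orchestration: scaling -> KPCA -> per-node hyperparameter
search -> per-node SVR training -> reconstruction -> MSE/RE/CC evaluation.

One regression model is built per cardiac node: its inputs are the KPCA
features of the scaled BSP rows (shared across nodes) and its target the
node's column of the row-scaled TMP matrix. Reconstruction applies the
same per-row scaling convention to test BSP rows (row scaling needs no
training statistics), projects through the stored KPCA model and stacks
the per-node predictions. Reports are computed in scaled units; unscaling
against known truth extremes is available for synthetic experiments.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data import (
    Hyperparameters,
    PotentialDataset,
    RunConfig,
    SearchResult,
    get_logger,
    log_record,
)
from .optimizers import fitness, make_svr_evaluator, search
from .preprocessing import (
    KPCAModel,
    ScalingParams,
    kpca_fit,
    kpca_transform,
    scale_rows,
)
from .svr import SVRModel, svr_predict, svr_train

__all__ = [
    "NodeModel",
    "ModelBank",
    "ReconstructionReport",
    "ComparisonResult",
    "train_model_bank",
    "reconstruct",
    "evaluate_reconstruction",
    "compare_methods",
    "save_bank",
    "load_bank",
]

_logger = get_logger("invecg.pipeline")


@dataclass(frozen=True)
class NodeModel:
    """Searched hyperparameters, trained SVR and search record for one node."""

    hyperparameters: Hyperparameters
    model: SVRModel
    result: SearchResult


@dataclass(frozen=True)
class ModelBank:
    """One regression model per TMP node plus the shared preprocessing state."""

    nodes: list[NodeModel]
    kpca: KPCAModel
    bsp_scaling: ScalingParams
    tmp_scaling: ScalingParams
    config: RunConfig
    n_leads: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def training_fitness(self) -> np.ndarray:
        return np.array([nm.result.best_fitness for nm in self.nodes])


def train_model_bank(
    train: PotentialDataset, config: RunConfig, progress: bool = False
) -> ModelBank:
    """Train the full per-node model bank on a training dataset.

    Scales BSP and TMP rows, fits KPCA on the scaled BSP block, then for
    each node runs the configured searcher (each node gets a distinct
    deterministic sub-seed derived from the run seed) and retrains a final
    SVR at the selected hyperparameters. Deterministic given the seed.
    """
    if train.n_times == 0:
        raise ValueError("empty training dataset")
    bsp_s, bsp_params = scale_rows(train.bsp)
    tmp_s, tmp_params = scale_rows(train.tmp)
    kpca = kpca_fit(bsp_s, d=config.kpca_dim, bandwidth=config.kpca_bandwidth)
    F = kpca_transform(kpca, bsp_s)

    nodes: list[NodeModel] = []
    for j in range(train.n_nodes):
        t0 = time.perf_counter()
        targets = tmp_s[:, j]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, j]))
        evaluator = make_svr_evaluator(
            F,
            targets,
            fitness_offset=config.fitness_offset,
            svr_tol=config.svr_tol,
            svr_max_iter=config.svr_max_iter,
            cv_folds=config.cv_folds,
        )
        result = search(config, evaluator, rng)
        hp = result.best
        model = svr_train(
            F,
            targets,
            hp.C,
            hp.sigma2,
            hp.epsilon,
            tol=config.svr_tol,
            max_iter=10 * config.svr_max_iter,
        )
        nodes.append(NodeModel(hyperparameters=hp, model=model, result=result))
        log_record(
            _logger,
            "node_trained",
            node=j,
            optimizer=config.optimizer,
            C=hp.C,
            sigma2=hp.sigma2,
            epsilon=hp.epsilon,
            fitness=result.best_fitness,
            seconds=round(time.perf_counter() - t0, 3),
        )
        if progress:
            print(f"node {j + 1}/{train.n_nodes}: fitness {result.best_fitness:.4f}%")
    return ModelBank(
        nodes=nodes,
        kpca=kpca,
        bsp_scaling=bsp_params,
        tmp_scaling=tmp_params,
        config=config,
        n_leads=train.n_leads,
    )


def reconstruct(bank: ModelBank, test_bsp: np.ndarray) -> np.ndarray:
    """Reconstruct scaled TMPs (test times x nodes) from raw test BSP rows.

    Test rows are scaled by their own per-row extremes (the scaling formula
    is per time instant and needs no training statistics), projected with
    the stored KPCA model, and predicted node by node.
    """
    test_bsp = np.asarray(test_bsp, dtype=float)
    if test_bsp.size == 0:
        return np.empty((0, bank.n_nodes))
    test_bsp = np.atleast_2d(test_bsp)
    if test_bsp.shape[1] != bank.n_leads:
        raise ValueError(
            f"expected {bank.n_leads} leads, got {test_bsp.shape[1]}"
        )
    scaled, _ = scale_rows(test_bsp)
    F = kpca_transform(bank.kpca, scaled)
    out = np.column_stack([svr_predict(nm.model, F) for nm in bank.nodes])
    return out


@dataclass(frozen=True)
class ReconstructionReport:
    """Per-test-time MSE / RE / CC and their aggregates.

    ``cc`` is NaN at times where the truth row has zero variance (Pearson
    undefined); those rows are excluded from ``m_cc``/``std_cc`` and
    counted in ``cc_excluded``. ``node_mean_pct``/``node_std_pct`` are the
    per-node mean and standard deviation over test times of the offset
    absolute-percentage error (the single-node time-course analogue).
    """

    mse: np.ndarray
    re: np.ndarray
    cc: np.ndarray
    m_mse: float
    std_mse: float
    m_re: float
    std_re: float
    m_cc: float
    std_cc: float
    cc_excluded: int
    node_mean_pct: np.ndarray
    node_std_pct: np.ndarray

    def summary(self) -> dict:
        return {
            "m_mse": self.m_mse,
            "std_mse": self.std_mse,
            "m_re": self.m_re,
            "std_re": self.std_re,
            "m_cc": self.m_cc,
            "std_cc": self.std_cc,
        }


def _pearson_rows(recon: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, int]:
    cc = np.full(truth.shape[0], np.nan)
    excluded = 0
    for i in range(truth.shape[0]):
        e = truth[i] - truth[i].mean()
        c = recon[i] - recon[i].mean()
        se = np.sqrt(e @ e)
        sc = np.sqrt(c @ c)
        if se == 0.0:
            excluded += 1
            continue
        if sc == 0.0:
            cc[i] = 0.0
            continue
        cc[i] = float((c @ e) / (sc * se))
    return cc, excluded


def _printed_cc_rows(recon: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, int]:
    # As-printed variant: the first normalizing factor centers the
    # reconstruction by the TRUTH mean. Not a true correlation; kept for
    # comparison only.
    cc = np.full(truth.shape[0], np.nan)
    excluded = 0
    for i in range(truth.shape[0]):
        eb = truth[i].mean()
        e = truth[i] - eb
        c = recon[i] - recon[i].mean()
        denom1 = np.sqrt(np.sum((recon[i] - eb) ** 2))
        denom2 = np.sqrt(e @ e)
        if denom2 == 0.0 or denom1 == 0.0:
            excluded += 1
            continue
        cc[i] = float((c @ e) / (denom1 * denom2))
    return cc, excluded


def evaluate_reconstruction(
    recon: np.ndarray,
    truth: np.ndarray,
    fitness_offset: float = 1.0,
    printed_cc: bool = False,
) -> ReconstructionReport:
    """Score a reconstruction against the truth, per test time instant.

    For each time t over the n nodes: MSE = mean squared difference,
    RE = ||recon - truth|| / ||truth||, CC = Pearson correlation (or the
    as-printed variant when ``printed_cc`` is set). Aggregates are the
    mean and (population) standard deviation over test times.
    """
    recon = np.atleast_2d(np.asarray(recon, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if recon.shape != truth.shape:
        raise ValueError(f"shape mismatch: {recon.shape} vs {truth.shape}")
    if truth.shape[1] < 2:
        raise ValueError("need >= 2 nodes per time instant for CC")
    diff = recon - truth
    mse = np.mean(diff**2, axis=1)
    truth_norm = np.linalg.norm(truth, axis=1)
    re = np.linalg.norm(diff, axis=1) / np.where(truth_norm == 0, 1.0, truth_norm)
    cc_fn = _printed_cc_rows if printed_cc else _pearson_rows
    cc, excluded = cc_fn(recon, truth)
    if excluded:
        log_record(_logger, "cc_excluded_rows", count=excluded)
    valid = ~np.isnan(cc)
    off = fitness_offset
    node_pct = np.abs(diff) / np.abs(truth + off) * 100.0
    return ReconstructionReport(
        mse=mse,
        re=re,
        cc=cc,
        m_mse=float(mse.mean()),
        std_mse=float(mse.std()),
        m_re=float(re.mean()),
        std_re=float(re.std()),
        m_cc=float(cc[valid].mean()) if valid.any() else float("nan"),
        std_cc=float(cc[valid].std()) if valid.any() else float("nan"),
        cc_excluded=excluded,
        node_mean_pct=node_pct.mean(axis=0),
        node_std_pct=node_pct.std(axis=0),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Method-comparison output: the aggregate table (one row per
    optimizer), per-node error table, full reports and banks, and the
    informational per-node mean search durations (seconds; excluded from
    the table so results remain bit-reproducible)."""

    table: pd.DataFrame
    per_node: pd.DataFrame
    reports: dict[str, ReconstructionReport]
    banks: dict[str, ModelBank]
    durations: dict[str, float]


def compare_methods(
    train: PotentialDataset,
    test: PotentialDataset,
    configs: Mapping[str, RunConfig],
    progress: bool = False,
) -> ComparisonResult:
    """Run the full pipeline once per optimizer config on identical splits
    and report m-/std- MSE/RE/CC per method plus per-node errors."""
    if not configs:
        raise ValueError("need at least one optimizer config")
    truth_scaled, _ = scale_rows(test.tmp)
    rows = {}
    per_node_cols = {}
    reports: dict[str, ReconstructionReport] = {}
    banks: dict[str, ModelBank] = {}
    durations: dict[str, float] = {}
    for name, cfg in configs.items():
        t0 = time.perf_counter()
        bank = train_model_bank(train, cfg, progress=progress)
        dur = (time.perf_counter() - t0) / max(train.n_nodes, 1)
        recon = reconstruct(bank, test.bsp)
        report = evaluate_reconstruction(
            recon, truth_scaled, fitness_offset=cfg.fitness_offset
        )
        rows[name] = report.summary()
        per_node_cols[f"{name}_mean_pct"] = report.node_mean_pct
        per_node_cols[f"{name}_std_pct"] = report.node_std_pct
        reports[name] = report
        banks[name] = bank
        durations[name] = dur
        log_record(_logger, "method_done", method=name,
                   mean_node_search_seconds=round(dur, 3), **report.summary())
    table = pd.DataFrame.from_dict(rows, orient="index")
    per_node = pd.DataFrame(per_node_cols)
    per_node.index.name = "node"
    return ComparisonResult(
        table=table, per_node=per_node, reports=reports, banks=banks,
        durations=durations,
    )


# ---------------------------------------------------------------------------
# Bank serialization (structured text)
# ---------------------------------------------------------------------------


def save_bank(bank: ModelBank, directory: str | Path) -> None:
    """Serialize a model bank to a directory of JSON text files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bank.config.to_yaml(d / "config.yaml")
    (d / "preprocessing.json").write_text(
        json.dumps(
            {
                "kpca": bank.kpca.to_dict(),
                "bsp_scaling": bank.bsp_scaling.to_dict(),
                "tmp_scaling": bank.tmp_scaling.to_dict(),
                "n_leads": bank.n_leads,
            }
        )
    )
    nodes = []
    for nm in bank.nodes:
        nodes.append(
            {
                "hyperparameters": {
                    "C": nm.hyperparameters.C,
                    "sigma2": nm.hyperparameters.sigma2,
                    "epsilon": nm.hyperparameters.epsilon,
                },
                "model": nm.model.to_dict(),
                "result": {
                    "best_fitness": nm.result.best_fitness,
                    "trajectory": nm.result.trajectory.tolist(),
                    "generations": nm.result.generations,
                    "evaluations": nm.result.evaluations,
                },
            }
        )
    (d / "nodes.json").write_text(json.dumps(nodes))


def load_bank(directory: str | Path) -> ModelBank:
    d = Path(directory)
    config = RunConfig.from_yaml(d / "config.yaml")
    pre = json.loads((d / "preprocessing.json").read_text())
    nodes_raw = json.loads((d / "nodes.json").read_text())
    nodes = []
    for nd in nodes_raw:
        hp = Hyperparameters(**nd["hyperparameters"])
        model = SVRModel.from_dict(nd["model"])
        res = SearchResult(
            best=hp,
            best_fitness=nd["result"]["best_fitness"],
            trajectory=np.asarray(nd["result"]["trajectory"], dtype=float),
            generations=nd["result"]["generations"],
            evaluations=nd["result"]["evaluations"],
        )
        nodes.append(NodeModel(hyperparameters=hp, model=model, result=res))
    return ModelBank(
        nodes=nodes,
        kpca=KPCAModel.from_dict(pre["kpca"]),
        bsp_scaling=ScalingParams.from_dict(pre["bsp_scaling"]),
        tmp_scaling=ScalingParams.from_dict(pre["tmp_scaling"]),
        config=config,
        n_leads=int(pre["n_leads"]),
    )
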