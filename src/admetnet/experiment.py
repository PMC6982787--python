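"""Experiment orchestration: cross-validation, holdout runs, the GSE audit
and the helper-task ablation.

Ties the pipeline together the way the study workflows do: build the label
matrix, split it (leave-cluster-out, matched random or time split), fit the
per-task scalers on the training portion only, train one model per fold,
and report per-fold and fold-averaged metrics.  Helper tasks always
contribute to the training loss but are excluded from headline averages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dense import DenseModel, DenseNetConfig
from .evaluation import GseConsistency, fold_report, gse_consistency, metrics_frame
from .gcn import GraphConvConfig, GraphConvModel
from .losses import LossConfig
from .mol import fingerprint_matrix, mol_to_graph
from .preprocess import AssayMatrix
from .splits import SplitPlan, cluster_split, random_split_matched, time_split
from .training import TrainConfig, predict, train

MODEL_KINDS = ("dense_single", "dense_multi", "gcn_single", "gcn_multi")


@dataclass
class ExperimentConfig:
    model: str = "gcn_multi"
    include_helpers: bool = True
    weighting: str = "balanced"       # simple | balanced
    per_minibatch: bool = False
    split: str = "cluster"            # cluster | random | time_taskwise | time_strict
    K: int = 10
    test_fold: int | None = None
    cutoff: str | None = None
    n_bits: int = 2048
    epochs: int | None = None         # None: the model's default
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODEL_KINDS:
            raise ValueError(f"model must be one of {MODEL_KINDS}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def subset_tasks(matrix: AssayMatrix, keep: np.ndarray) -> AssayMatrix:
    """Restrict a matrix to a boolean selection of tasks."""
    keep = np.asarray(keep, bool)
    return dataclasses.replace(
        matrix,
        endpoint_codes=[c for c, k in zip(matrix.endpoint_codes, keep) if k],
        specs=[s for s, k in zip(matrix.specs, keep) if k],
        values=matrix.values[:, keep], mask=matrix.mask[:, keep],
        dates=matrix.dates[:, keep],
        scalers=None if matrix.scalers is None else matrix.scalers[keep])


def build_features(molecules, model_kind: str, n_bits: int = 2048):
    if model_kind.startswith("dense"):
        return fingerprint_matrix(molecules, n_bits)
    return [mol_to_graph(m) for m in molecules]


def build_model(model_kind: str, n_tasks: int, seed: int, n_bits: int = 2048,
                epochs: int | None = None, **overrides):
    rng = np.random.default_rng(seed)
    if model_kind.startswith("dense"):
        cfg = DenseNetConfig(n_inputs=n_bits, n_tasks=n_tasks, **overrides)
        if epochs is not None:
            cfg.epochs = epochs
        return DenseModel(cfg, rng)
    cfg = GraphConvConfig(n_tasks=n_tasks, **overrides)
    if epochs is not None:
        cfg.epochs = epochs
    return GraphConvModel(cfg, rng)


def make_plan(matrix: AssayMatrix, config: ExperimentConfig,
              fps: np.ndarray | None = None) -> SplitPlan:
    """Build the split the config asks for; cluster/random need fingerprints."""
    if config.split in ("cluster", "random"):
        if fps is None:
            raise ValueError("cluster/random splits need the fingerprint matrix")
        plan = cluster_split(fps, matrix.mask, matrix.compound_ids, K=config.K,
                             seed=config.seed, test_fold=config.test_fold)
        if config.split == "random":
            plan = random_split_matched(plan, matrix.mask, seed=config.seed)
        return plan
    if config.split in ("time_taskwise", "time_strict"):
        if config.cutoff is None:
            raise ValueError("time splits require a cutoff date")
        return time_split(matrix, config.cutoff, strict=config.split == "time_strict",
                          seed=config.seed)
    raise ValueError(f"unknown split strategy {config.split!r}")


def _fit_and_eval(matrix: AssayMatrix, features, train_cells: np.ndarray,
                  eval_cells: np.ndarray, config: ExperimentConfig,
                  fold: int | str) -> tuple[pd.DataFrame, np.ndarray]:
    """Train one model on `train_cells`, return metrics on `eval_cells`
    and destandardized predictions for all compounds."""
    assert not (train_cells & eval_cells).any(), "leakage: train and eval cells overlap"
    std = matrix.standardized(train_mask=train_cells)
    task_sizes = train_cells.sum(axis=0)
    loss_cfg = LossConfig(weighting=config.weighting, task_sizes=task_sizes,
                          per_minibatch=config.per_minibatch)
    model = build_model(config.model, matrix.n_tasks, seed=config.seed,
                        n_bits=config.n_bits, epochs=config.epochs)
    train_rows = train_cells.any(axis=1)
    row_idx = np.flatnonzero(train_rows)
    sub_features = features[row_idx] if isinstance(features, np.ndarray) else \
        [features[i] for i in row_idx]
    targets = np.nan_to_num(std.values, nan=0.0)
    train(model, sub_features, targets[row_idx], train_cells[row_idx],
          TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                      seed=config.seed, loss=loss_cfg))
    pred_std = predict(model, features)
    pred = pred_std * std.scalers[:, 1] + std.scalers[:, 0]  # transformed scale
    frame = metrics_frame(pred, matrix.values, eval_cells, matrix.endpoint_codes, fold=fold)
    frame["helper"] = frame["endpoint"].map(
        {s.code: s.helper for s in matrix.specs})
    return frame, pred


@dataclass
class CrossValReport:
    per_fold: pd.DataFrame
    averaged: pd.DataFrame      # headline endpoints only (helpers excluded)
    averaged_all: pd.DataFrame  # including helper tasks


def run_crossvalidation(matrix: AssayMatrix, features, config: ExperimentConfig,
                        plan: SplitPlan | None = None,
                        fps: np.ndarray | None = None) -> CrossValReport:
    """Leave-one-fold-out cross-validation with per-fold scaler refits."""
    if not config.include_helpers:
        matrix = subset_tasks(matrix, ~matrix.helper_flags())
        # features are per-compound, unaffected by task subsetting
    if config.model.endswith("_single"):
        return _run_cv_single(matrix, features, config, plan, fps)
    if plan is None:
        if fps is None and isinstance(features, np.ndarray):
            fps = features
        plan = make_plan(matrix, config, fps)
    frames = []
    for fold, train_cells, val_cells in plan.cv_masks(matrix.mask):
        frame, _ = _fit_and_eval(matrix, features, train_cells, val_cells, config, fold)
        frames.append(frame)
    per_fold = pd.concat(frames, ignore_index=True)
    headline = per_fold[~per_fold["helper"]]
    return CrossValReport(per_fold=per_fold, averaged=fold_report(headline),
                          averaged_all=fold_report(per_fold))


def _run_cv_single(matrix, features, config, plan, fps=None):
    """Single-task variant: one model per non-helper endpoint."""
    multi_kind = config.model.replace("_single", "_multi")
    frames = []
    for t, spec in enumerate(matrix.specs):
        if spec.helper:
            continue
        sub = subset_tasks(matrix, np.arange(matrix.n_tasks) == t)
        sub_cfg = dataclasses.replace(config, model=multi_kind, weighting="simple")
        task_plan = plan if plan is not None else make_plan(
            sub, sub_cfg, fps if fps is not None else
            (features if isinstance(features, np.ndarray) else None))
        report = run_crossvalidation(sub, features, sub_cfg, plan=task_plan)
        frames.append(report.per_fold)
    per_fold = pd.concat(frames, ignore_index=True)
    return CrossValReport(per_fold=per_fold, averaged=fold_report(per_fold),
                          averaged_all=fold_report(per_fold))


def run_holdout(matrix: AssayMatrix, features, config: ExperimentConfig,
                plan: SplitPlan) -> tuple[pd.DataFrame, np.ndarray]:
    """Train on the plan's training side, evaluate on its test side.

    Returns the per-task test metrics and the full prediction matrix on
    the transformed (model) scale.
    """
    train_cells, test_cells = plan.holdout_masks(matrix.mask)
    return _fit_and_eval(matrix, features, train_cells, test_cells, config, fold="test")


def run_gse_audit(matrix: AssayMatrix, predictions: np.ndarray,
                  rows: np.ndarray | None = None) -> GseConsistency:
    """GSE consistency of a prediction matrix (transformed scale).

    Uses the melting-point (LMP), neutral logD (LOD) and DMSO solubility
    (LOO) columns.  ``rows`` selects the compound subset (e.g. the test
    fold); measured correlations use compounds with all three endpoints
    labeled.
    """
    codes = matrix.endpoint_codes
    try:
        i_lmp, i_lod, i_loo = codes.index("LMP"), codes.index("LOD"), codes.index("LOO")
    except ValueError as exc:
        raise ValueError("GSE audit needs LMP, LOD and LOO endpoints") from exc
    rows = np.ones(matrix.n_compounds, bool) if rows is None else np.asarray(rows, bool)
    pred = predictions[rows]
    all_measured = rows & matrix.mask[:, [i_lmp, i_lod, i_loo]].all(axis=1)
    kwargs = {}
    if all_measured.sum() >= 3:
        kwargs = dict(measured_lmp=matrix.values[all_measured, i_lmp],
                      measured_logd=matrix.values[all_measured, i_lod],
                      measured_logs=matrix.values[all_measured, i_loo])
    return gse_consistency(pred[:, i_lmp], pred[:, i_lod], pred[:, i_loo], **kwargs)


def helper_task_ablation(matrix: AssayMatrix, features, config: ExperimentConfig,
                         seeds: list[int], plan: SplitPlan) -> pd.DataFrame:
    """Compare headline-task test metrics with and without helper tasks.

    One model pair per seed on the same holdout plan; returns a tidy frame
    with the seed-averaged difference appended.
    """
    rows = []
    for seed in seeds:
        for include in (True, False):
            cfg = dataclasses.replace(config, include_helpers=include, seed=seed)
            m = matrix if include else subset_tasks(matrix, ~matrix.helper_flags())
            frame, _ = run_holdout(m, features, cfg, plan)
            frame = frame[~frame["helper"]].copy()
            frame["seed"] = seed
            frame["helpers"] = include
            rows.append(frame)
    tidy = pd.concat(rows, ignore_index=True)
    pivot = tidy.pivot_table(index="endpoint", columns="helpers",
                             values=["r2", "spearman_rho"], aggfunc="mean")
    summary = pd.DataFrame({
        "endpoint": pivot.index,
        "r2_with_helpers": pivot[("r2", True)].to_numpy(),
        "r2_without_helpers": pivot[("r2", False)].to_numpy(),
        "delta_r2": (pivot[("r2", True)] - pivot[("r2", False)]).to_numpy(),
        "delta_spearman": (pivot[("spearman_rho", True)]
                           - pivot[("spearman_rho", False)]).to_numpy(),
    }).reset_index(drop=True)
    return summary
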