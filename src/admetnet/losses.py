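"""Masked multitask mean-squared-error loss.

Each task contributes the MSE over its *labeled* cells in the minibatch;
missing labels never participate.  Tasks with no label in a batch are
dropped from the average.  Two weightings combine the per-task losses:

- ``simple``: every task present in the batch receives weight 1/N, N being
  the number of present tasks;
- ``balanced``: weights proportional to 1/task_size, so small tasks are
  upweighted.  By default the sizes are the global training-set task sizes;
  ``per_minibatch=True`` switches to the label counts inside the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor


@dataclass
class LossConfig:
    weighting: str = "simple"            # "simple" | "balanced"
    task_sizes: np.ndarray | None = None  # global training-set counts (balanced)
    per_minibatch: bool = False

    def __post_init__(self):
        if self.weighting not in ("simple", "balanced"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.weighting == "balanced" and not self.per_minibatch and self.task_sizes is None:
            raise ValueError("balanced weighting requires task_sizes (or per_minibatch=True)")


def task_weights(mask: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Per-task weights (summing to 1 over present tasks, 0 for absent)."""
    counts = mask.sum(axis=0)
    present = counts > 0
    if not present.any():
        raise ValueError("batch has no labeled cell in any task")
    weights = np.zeros(mask.shape[1])
    if cfg.weighting == "simple":
        weights[present] = 1.0 / present.sum()
    else:
        sizes = counts if cfg.per_minibatch else np.asarray(cfg.task_sizes, dtype=float)
        if np.any(sizes[present] <= 0):
            raise ValueError("task_sizes must be positive for present tasks")
        inv = np.zeros(mask.shape[1])
        inv[present] = 1.0 / sizes[present]
        weights = inv / inv.sum()
    return weights


def masked_multitask_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray,
                         cfg: LossConfig | None = None) -> float:
    """Weighted average of per-task MSEs over labeled cells (NumPy scalar)."""
    cfg = cfg or LossConfig()
    pred, mask = np.asarray(pred, float), np.asarray(mask, bool)
    target = np.where(mask, np.asarray(target, float), 0.0)
    if pred.shape != target.shape or pred.shape != mask.shape:
        raise ValueError("pred, target and mask shapes must agree")
    weights = task_weights(mask, cfg)
    counts = mask.sum(axis=0)
    sq = np.where(mask, (pred - target) ** 2, 0.0).sum(axis=0)
    per_task = np.divide(sq, counts, out=np.zeros_like(sq), where=counts > 0)
    return float((weights * per_task).sum())


def masked_mse_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray,
                    cfg: LossConfig | None = None) -> Tensor:
    """Differentiable version of :func:`masked_multitask_mse`.

    The task weights depend only on the mask and configuration, so they are
    constants with respect to the predictions; gradients are exactly zero
    at unlabeled cells.
    """
    cfg = cfg or LossConfig()
    mask = np.asarray(mask, bool)
    target = np.where(mask, np.asarray(target, float), 0.0)
    weights = task_weights(mask, cfg)
    counts = mask.sum(axis=0)
    scale = np.divide(weights, counts, out=np.zeros_like(weights), where=counts > 0)
    diff = pred - Tensor(target)
    sq = diff * diff * Tensor(mask.astype(float))
    return (sq.sum(axis=0) * Tensor(scale)).sum()
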