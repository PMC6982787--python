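"""Minibatch training of the dense and graph-convolution models.

Compounds are shuffled each epoch and batched uniformly (the masked loss
takes care of tasks missing from a batch).  Targets are on the
standardized scale; the loss is the weighted masked multitask MSE.  All
randomness (shuffling, dropout, input noise) flows from a single seeded
generator, so a fixed seed reproduces a run bit-identically on one device.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dense import DenseModel, input_noise
from .gcn import GraphConvModel, pack_graphs
from .losses import LossConfig, masked_mse_loss, masked_multitask_mse

__all__ = ["TrainConfig", "TrainingDiverged", "TrainingResult", "train"]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    epochs: int | None = None      # None: use the model config's value
    batch_size: int | None = None
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)


@dataclass
class TrainingResult:
    model: object
    curve: pd.DataFrame   # per-epoch mean training loss (and validation loss)
    n_steps: int


def _make_batch_inputs(model, features, idx, training, rng):
    if isinstance(model, DenseModel):
        counts = features[idx]
        p = model.config.input_noise_p if training else 0.0
        return input_noise(counts, p=p, rng=rng)
    if isinstance(model, GraphConvModel):
        return pack_graphs([features[i] for i in idx])
    raise TypeError(f"unsupported model type {type(model).__name__}")


def train(model, features, targets: np.ndarray, mask: np.ndarray,
          config: TrainConfig | None = None,
          val_features=None, val_targets=None, val_mask=None) -> TrainingResult:
    """Train a model on masked multitask targets.

    Parameters
    ----------
    features:
        Fingerprint count matrix (dense model) or list of
        :class:`~admetnet.mol.MolecularGraph` (graph model), one entry per
        compound, aligned with ``targets`` rows.
    targets, mask:
        Standardized label matrix and its label mask, shape (n, T).
    """
    config = config or TrainConfig()
    targets = np.asarray(targets, float)
    mask = np.asarray(mask, bool)
    n = targets.shape[0]
    if (isinstance(features, np.ndarray) and features.shape[0] != n) or \
            (not isinstance(features, np.ndarray) and len(features) != n):
        raise ValueError("features and targets must align")
    if not mask.any():
        raise ValueError("no labeled cells to train on")

    epochs = config.epochs if config.epochs is not None else model.config.epochs
    batch_size = config.batch_size if config.batch_size is not None else model.config.batch_size
    rng = np.random.default_rng(config.seed)
    optimizer = model.make_optimizer()

    rows = []
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch_mask = mask[idx]
            if not batch_mask.any():
                continue
            inputs = _make_batch_inputs(model, features, idx, training=True, rng=rng)
            pred = model.forward(inputs, training=True, rng=rng)
            loss = masked_mse_loss(pred, targets[idx], batch_mask, config.loss)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(f"loss became {loss.data} at step {step}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
            step += 1
        row = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_features is not None:
            val_pred = predict(model, val_features)
            row["val_loss"] = masked_multitask_mse(val_pred, val_targets, val_mask, config.loss)
        rows.append(row)
    return TrainingResult(model=model, curve=pd.DataFrame(rows), n_steps=step)


def predict(model, features) -> np.ndarray:
    """Model predictions on the standardized scale for a full feature set."""
    if isinstance(model, DenseModel):
        return model.predict(np.asarray(features))
    return model.predict(list(features))
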