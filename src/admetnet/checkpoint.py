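"""Model checkpoints: weights + config + per-task scalers in one archive.

The archive is a NumPy ``.npz`` holding every parameter array, the scaler
matrix and endpoint codes, plus a JSON-encoded model configuration, so a
checkpoint is self-describing and reloads without the training script.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._autograd import Tensor
from .dense import DenseModel, DenseNetConfig
from .gcn import GraphConvConfig, GraphConvModel


def save_checkpoint(path, model, scalers: np.ndarray | None = None,
                    endpoint_codes: list[str] | None = None) -> None:
    meta = {
        "kind": model.kind,
        "config": dataclasses.asdict(model.config),
        "endpoint_codes": endpoint_codes or [],
    }
    arrays = {f"param/{k}": p.data for k, p in model.params.items()}
    if scalers is not None:
        arrays["scalers"] = np.asarray(scalers)
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Returns (model, scalers, endpoint_codes)."""
    archive = np.load(path)
    meta = json.loads(archive["meta"].tobytes().decode())
    cfg = meta["config"]
    for key in ("hidden_dims", "dropout", "conv_dims"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    rng = np.random.default_rng(0)
    if meta["kind"] == "dense":
        model = DenseModel(DenseNetConfig(**cfg), rng)
    else:
        model = GraphConvModel(GraphConvConfig(**cfg), rng)
    for key in archive.files:
        if key.startswith("param/"):
            model.params[key[len("param/"):]] = Tensor(archive[key], requires_grad=True)
    scalers = archive["scalers"] if "scalers" in archive.files else None
    return model, scalers, meta["endpoint_codes"]
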