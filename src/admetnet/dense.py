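"""Fingerprint-based fully connected networks with the input-noise scheme.

The architecture is a pyramid of four ReLU hidden layers (2000, 1000, 500,
100) on top of folded ECFC6 count fingerprints, with dropout 0.5/0.5/0.25/0
on the hidden activations, He weight initialization, zero hidden biases and
an output bias of −1.

Because count fingerprints are sparse, input dropout would mostly hit
zeros.  Instead, during training each fingerprint element is *replaced*,
with probability p, by a synthetic count |round(N(0, 3))| — randomly
"dropping in" chemical features — and a tanh squashes the counts
afterwards.  At inference p is forced to 0 and only the tanh remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor
from .nn import Adam, constant, he_normal, zeros

NOISE_SD = 3.0  # sd of the zero-mean normal generating replacement counts


@dataclass
class DenseNetConfig:
    n_inputs: int = 2048
    hidden_dims: tuple[int, ...] = (2000, 1000, 500, 100)
    dropout: tuple[float, ...] = (0.5, 0.5, 0.25, 0.0)
    input_noise_p: float = 0.01
    output_bias_init: float = -1.0
    n_tasks: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 40
    weight_decay: float = 1e-5
    lr_decay_every: int | None = 1000
    lr_decay_factor: float = 0.95

    def __post_init__(self):
        if len(self.dropout) != len(self.hidden_dims):
            raise ValueError("dropout must give one rate per hidden layer")
        if not 0.0 <= self.input_noise_p <= 1.0:
            raise ValueError("input_noise_p must lie in [0, 1]")


def noise_counts(shape, rng: np.random.Generator) -> np.ndarray:
    """Synthetic fingerprint counts: |round(N(0, 3))|, elementwise."""
    return np.abs(np.round(noise_normal(shape, rng)))


def noise_normal(shape, rng: np.random.Generator) -> np.ndarray:
    """The pre-rounding noise source: draws from N(0, NOISE_SD)."""
    return rng.normal(0.0, NOISE_SD, size=shape)


def input_noise(counts: np.ndarray, p: float, rng: np.random.Generator | None = None,
                apply_tanh: bool = True) -> np.ndarray:
    """Randomly replace fingerprint counts with synthetic ones, then tanh.

    With probability ``p`` (independently per element) a count is replaced
    by ``|round(N(0, 3))|``; a tanh is applied afterwards to smooth the
    counts.  ``p = 0`` (the inference setting) reduces to ``tanh(counts)``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("fingerprint counts must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError("replacement probability must lie in [0, 1]")
    if p > 0.0:
        if rng is None:
            raise ValueError("a random generator is required when p > 0")
        replace = rng.random(counts.shape) < p
        counts = np.where(replace, noise_counts(counts.shape, rng), counts)
    return np.tanh(counts) if apply_tanh else counts


class DenseModel:
    """Pyramidal fully connected regression network with task heads."""

    kind = "dense"

    def __init__(self, config: DenseNetConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, Tensor] = {}
        dims = [config.n_inputs, *config.hidden_dims]
        for i, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            self.params[f"W{i}"] = he_normal(rng, fan_in, fan_out)
            self.params[f"b{i}"] = zeros(fan_out)
        self.params["W_out"] = he_normal(rng, dims[-1], config.n_tasks)
        self.params["b_out"] = constant(config.output_bias_init, config.n_tasks)

    def forward(self, x: np.ndarray | Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Forward pass on pre-squashed inputs (after :func:`input_noise`).

        Dropout is active only when ``training`` is True (inverted dropout,
        so inference needs no rescaling).
        """
        h = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        for i, rate in enumerate(self.config.dropout):
            h = (h @ self.params[f"W{i}"] + self.params[f"b{i}"]).relu()
            if training and rate > 0.0:
                if rng is None:
                    raise ValueError("training-mode dropout requires a random generator")
                keep = (rng.random(h.shape) >= rate) / (1.0 - rate)
                h = h * Tensor(keep)
        return h @ self.params["W_out"] + self.params["b_out"]

    def predict(self, counts: np.ndarray) -> np.ndarray:
        """Inference: tanh-squashed fingerprints, no noise, no dropout."""
        x = input_noise(np.atleast_2d(counts), p=0.0)
        return self.forward(x, training=False).data

    def make_optimizer(self) -> Adam:
        cfg = self.config
        return Adam(self.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
                    lr_decay_every=cfg.lr_decay_every, lr_decay_factor=cfg.lr_decay_factor)
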