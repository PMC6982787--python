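"""Shared neural-network utilities: initialization and Adam optimization."""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor


def he_normal(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """He initialization for ReLU layers: N(0, sqrt(2 / fan_in))."""
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)),
                  requires_grad=True)


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def constant(value: float, *shape) -> Tensor:
    return Tensor(np.full(shape, float(value)), requires_grad=True)


class Adam:
    """Adam with optional L2 weight decay and stepwise exponential lr decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 lr_decay_every: int | None = None, lr_decay_factor: float = 0.95):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_decay_every = lr_decay_every
        self.lr_decay_factor = lr_decay_factor
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    @property
    def current_lr(self) -> float:
        if not self.lr_decay_every:
            return self.lr
        return self.lr * self.lr_decay_factor ** (self.t // self.lr_decay_every)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases
                g = g + self.weight_decay * p.data
            self._m[k] = self.beta1 * self._m[k] + (1 - self.beta1) * g
            self._v[k] = self.beta2 * self._v[k] + (1 - self.beta2) * g * g
            m_hat = self._m[k] / (1 - self.beta1 ** self.t)
            v_hat = self._v[k] / (1 - self.beta2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
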