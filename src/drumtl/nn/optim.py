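"""Adam optimiser and step learning-rate decay."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "StepDecay"]


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 0.005,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class StepDecay:
    """Multiply the learning rate by ``factor`` every ``every`` epochs."""

    def __init__(self, optimizer: Adam, every: int = 10, factor: float = 0.5):
        self.optimizer = optimizer
        self.every = max(1, every)
        self.factor = factor
        self._initial_lr = optimizer.lr

    def at_epoch(self, epoch: int) -> None:
        self.optimizer.lr = self._initial_lr * self.factor ** (epoch // self.every)
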