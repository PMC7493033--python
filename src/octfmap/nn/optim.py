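"""Momentum-based stochastic gradient descent."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["SGD"]


class SGD:
    """SGD with classical momentum: v <- mu*v + g; p <- p - lr*v."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
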