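"""Stochastic gradient descent with momentum, and the poly learning-rate rule."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "poly_lr"]


def poly_lr(lr0: float, t: int, total: int, power: float = 0.9) -> float:
    """lr(t) = lr0 * (1 - t/total)**power; reaches 0 at t == total."""
    if total <= 0:
        raise ValueError("total iterations must be positive")
    frac = min(max(t / total, 0.0), 1.0)
    return lr0 * (1.0 - frac) ** power


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
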