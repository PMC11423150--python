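"""Optimizers and gradient clipping for the numpy autodiff stack."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "clip_grad_value"]


class Adam:
    """ADAM with optional decoupled L2 weight decay.

    Parameters mirror the common deep-learning defaults; `betas` and
    `weight_decay` are exposed because the adversarial stage uses
    non-default values (betas=(0.5, 0.9), weight decay 1e-5).
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_value(params: list[Tensor], clip_value: float):
    """Clamp every gradient element to [-clip_value, clip_value] in place."""
    for p in params:
        if p.grad is not None:
            np.clip(p.grad, -clip_value, clip_value, out=p.grad)
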