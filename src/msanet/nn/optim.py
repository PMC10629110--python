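"""Adaptive-moment-estimation (Adam) optimizer."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates.

    Parameters
    ----------
    params : iterable of Tensor
        Trainable tensors; their ``.grad`` fields are consumed by ``step``.
    lr : float
        Step size (default 3e-4, the network's training default).
    betas, eps : float
        Exponential decay rates for the moment estimates and the
        denominator floor.
    """

    def __init__(self, params, lr: float = 3e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
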