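"""Optimizers for the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor


class Adam:
    """Adam with an optional step-wise learning-rate halving schedule.

    Parameters
    ----------
    params
        Trainable tensors to update.
    lr
        Base learning rate.
    halve_every
        If set, the learning rate is halved after every ``halve_every`` calls
        to :meth:`step` (one call per epoch in the training loops).
    """

    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999),
                 eps: float = 1e-8, halve_every: int | None = None):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.halve_every = halve_every
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    @property
    def current_lr(self) -> float:
        if not self.halve_every:
            return self.lr
        return self.lr * 0.5 ** (self.t // self.halve_every)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        lr = self.current_lr
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
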