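"""Optimizers for training the segmentation network."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / (1.0 - b1 ** self.t)
            vhat = v / (1.0 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype, copy=False)


class SGD:
    """Plain stochastic gradient descent (used mainly in tests)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= (self.lr * p.grad).astype(p.data.dtype, copy=False)
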