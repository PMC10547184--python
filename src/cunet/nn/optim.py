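"""Stochastic gradient descent with classical momentum and L2 weight decay."""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, params, lr: float = 1e-3, momentum: float = 0.9,
                 weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
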