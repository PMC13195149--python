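"""Stochastic gradient descent with momentum and decoupled weight decay."""
from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.937, weight_decay=0.0005, nesterov=True):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.nesterov = nesterov
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:  # decay conv/linear weights only
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            upd = g + self.momentum * v if self.nesterov else v
            p.data -= self.lr * upd

    def zero_grad(self):
        for p in self.params:
            p.grad = None
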