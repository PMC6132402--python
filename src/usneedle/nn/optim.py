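"""First-order optimizers operating on lists of :class:`~usneedle.nn.Param`."""

from __future__ import annotations

import numpy as np


class RMSProp:
    """SGD with the learning rate divided by the exponentially weighted
    average of recent squared gradients."""

    def __init__(self, params, lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, c in zip(self.params, self._cache):
            c *= self.rho
            c += (1.0 - self.rho) * p.grad ** 2
            p.value -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adaptive-moment stochastic gradient descent."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
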