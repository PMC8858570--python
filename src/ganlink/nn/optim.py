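"""Adam optimizer operating directly on parameter arrays."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.99, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape, dtype=DTYPE) for p in self.params]
        self.v = [np.zeros(p.shape, dtype=DTYPE) for p in self.params]

    def step(self, grads) -> None:
        """Apply one update; ``grads`` aligns with the parameter list."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
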