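"""Minimal Adam optimizer over plain NumPy arrays.

Used both for iterative pose refinement (6 parameters, per-group step sizes)
and for training the initialization CNN (layer parameter lists).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Standard Adam with bias correction.

    ``params`` is a list of arrays updated in place; ``lr`` may be a scalar
    or a per-array list (e.g. separate rotation/translation step sizes).
    """

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        if np.isscalar(lr):
            lr = [float(lr)] * len(self.params)
        if len(lr) != len(self.params):
            raise ValueError("need one learning rate per parameter array")
        self.lr = [np.asarray(l, dtype=float) for l in lr]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=float) for p in self.params]
        self.v = [np.zeros_like(p, dtype=float) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        """One update from gradients matching ``params`` (minimization)."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v, lr in zip(self.params, grads, self.m, self.v, self.lr):
            g = np.asarray(g, dtype=float)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
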