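"""Optimizers (Adam only; that is what both training stages use)."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    """Adam with the standard bias correction; skips frozen layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.layers):
            if not layer.trainable:
                continue
            for key, p in layer.params.items():
                g = layer.grads[key]
                sk = (i, key)
                m = self._m.setdefault(sk, np.zeros_like(p))
                v = self._v.setdefault(sk, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
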