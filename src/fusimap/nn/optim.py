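"""Adam optimizer for the NumPy layers."""

from __future__ import annotations

from typing import List

import numpy as np

from .ops import Layer, collect_params


class Adam:
    def __init__(
        self,
        layers: List[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.entries = collect_params(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.P[k]) for layer, k in self.entries]
        self.v = [np.zeros_like(layer.P[k]) for layer, k in self.entries]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, k) in enumerate(self.entries):
            g = layer.G[k]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.P[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.P[k].dtype
            )

    def zero_grad(self) -> None:
        for layer, _ in self.entries:
            layer.zero_grad()
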