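"""AdamW with decoupled weight decay and a cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter).

    The update is ``p -= lr * (mhat / (sqrt(vhat) + eps) + weight_decay * p)``;
    the decay term is applied to the raw parameter, outside the adaptive
    moment rescaling.
    """

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update


def cosine_lr(step: int, total_steps: int, lr0: float, final_fraction: float = 0.01) -> float:
    """Cosine decay from ``lr0`` to ``lr0 * final_fraction`` over the run."""
    if total_steps <= 1:
        return lr0
    progress = min(step, total_steps - 1) / (total_steps - 1)
    lr_min = lr0 * final_fraction
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * progress))
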