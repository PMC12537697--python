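"""Selective-kernel fusion of a skip-connection feature with the main path.

Per-channel softmax weights are derived from the global-average-pooled sum of
the two branches through a bottleneck MLP of two pointwise convolutions::

    s        = GAP(x1 + x2)
    (w1, w2) = split(softmax(PW(ReLU(PW(s)))))     # softmax over the 2 branches
    y        = w1 * x1 + w2 * x2

Because the weights are a softmax over the two branches they sum to one per
channel, so the output is a per-channel convex combination — in contrast to
the independent sigmoid gates inside MixConv.
"""

from __future__ import annotations

import numpy as np

from .. import nn


class SKFusion(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 8):
        super().__init__()
        C = channels
        self.channels = C
        d = max(C // reduction, 4)
        self.reduce = nn.conv1x1(C, d, rng, bias=False)
        self.expand = nn.conv1x1(d, 2 * C, rng, bias=False)

    def weights(self, x1: nn.Tensor, x2: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Per-channel fusion weights (each N x C x 1 x 1, summing to 1)."""
        if x1.shape != x2.shape:
            raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
        s = nn.global_avg_pool(x1 + x2)
        logits = self.expand(self.reduce(s).relu())
        n = logits.shape[0]
        stacked = logits.reshape(n, 2, self.channels, 1, 1)
        w = nn.softmax(stacked, axis=1)
        return w[:, 0], w[:, 1]

    def forward(self, x1: nn.Tensor, x2: nn.Tensor) -> nn.Tensor:
        w1, w2 = self.weights(x1, x2)
        return w1 * x1 + w2 * x2
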