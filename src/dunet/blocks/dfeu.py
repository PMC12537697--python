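"""Dehazing Feature Extraction Unit (DFEU).

The unit carries the atmospheric scattering model into feature space.  Two
branches estimate, from a hazy feature map I_f, a (spatially varying)
atmospheric-light feature A_f and a transmission feature t_f, both bounded in
(0, 1) by terminal sigmoids; the dehazed feature is their algebraic
combination

    J_f = (I_f - A_f) / (t_f + eps) + A_f,

the feature-space inverse of I = J*t + A*(1-t).  The atmospheric branch uses
a pair of 1x11 / 11x1 depthwise strip convolutions for long-range context at
low cost; the transmission branch pools the input over a 1/2/4 spatial
pyramid, resizes bilinearly, and squeezes the concatenated maps through a
two-layer pointwise bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn


@dataclass(frozen=True)
class DFEUParams:
    channels: int
    strip_kernel: int = 11
    pyramid_sizes: tuple[int, ...] = (1, 2, 4)
    hidden_ratio: float = 1.5   # pointwise bottleneck width as a fraction of C
    epsilon: float = 1e-3       # division stabilizer on the transmission feature

    def __post_init__(self):
        if list(self.pyramid_sizes) != sorted(set(self.pyramid_sizes)):
            raise ValueError("pyramid sizes must be strictly increasing")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")

    @property
    def hidden(self) -> int:
        return max(int(self.channels * self.hidden_ratio), 4)


class DFEU(nn.Module):
    def __init__(self, p: DFEUParams, rng: np.random.Generator):
        super().__init__()
        C, k = p.channels, p.strip_kernel
        self.p = p
        # atmospheric-light branch
        self.a_conv_in = nn.conv_same(C, C, 3, rng)
        self.a_strip_h = nn.Conv2d(C, C, (1, k), rng, padding=(0, k // 2), groups=C)
        self.a_strip_v = nn.Conv2d(C, C, (k, 1), rng, padding=(k // 2, 0), groups=C)
        self.a_conv_mid = nn.conv_same(C, C, 3, rng)
        self.a_bn = nn.BatchNorm2d(C)
        self.a_conv_out = nn.conv1x1(C, C, rng)
        # transmission branch
        self.t_reduce = nn.conv1x1(len(p.pyramid_sizes) * C, p.hidden, rng)
        self.t_expand = nn.conv1x1(p.hidden, C, rng)

    def estimate_atmospheric(self, feat: nn.Tensor) -> nn.Tensor:
        """A_f in (0, 1), same shape as the input feature."""
        h = self.a_conv_in(feat)
        h = self.a_strip_v(self.a_strip_h(h))
        h = self.a_bn(self.a_conv_mid(h)).relu()
        return self.a_conv_out(h).sigmoid()

    def estimate_transmission(self, feat: nn.Tensor) -> nn.Tensor:
        """t_f in (0, 1), C channels, from the 1/2/4 pooling pyramid."""
        _, _, h, w = feat.shape
        if h < max(self.p.pyramid_sizes) or w < max(self.p.pyramid_sizes):
            raise ValueError(
                f"spatial dims ({h}x{w}) smaller than the pooling pyramid "
                f"{self.p.pyramid_sizes}"
            )
        branches = [
            nn.resize_bilinear(nn.adaptive_avg_pool2d(feat, g), (h, w))
            for g in self.p.pyramid_sizes
        ]
        t1 = nn.cat(branches, axis=1)
        return self.t_expand(self.t_reduce(t1).relu()).sigmoid()

    def forward(self, feat: nn.Tensor) -> nn.Tensor:
        a = self.estimate_atmospheric(feat)
        t = self.estimate_transmission(feat)
        return dfeu_reconstruct(feat, a, t, self.p.epsilon)


def dfeu_reconstruct(i_feat: nn.Tensor, a_feat: nn.Tensor, t_feat: nn.Tensor,
                     epsilon: float = 0.0) -> nn.Tensor:
    """Feature-space ASM inversion: J_f = (I_f - A_f) / (t_f + eps) + A_f."""
    if i_feat.shape != a_feat.shape or i_feat.shape != t_feat.shape:
        raise ValueError(
            f"shape mismatch: {i_feat.shape} vs {a_feat.shape} vs {t_feat.shape}"
        )
    if np.any(t_feat.data + epsilon <= 0):
        raise ValueError("transmission feature plus epsilon must be positive")
    return (i_feat - a_feat) / (t_feat + epsilon) + a_feat
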