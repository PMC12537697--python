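"""MixConv: a residual block mixing gated, local and dilated convolution paths.

Computation order::

    xb = BatchNorm(x)
    x1 = sigmoid(PW_g(xb)) * DW_local(PW_v(xb))          # gated separable path
    x2 = DW_ms(ReLU(IN(PW(x1))))                         # local branch
    x3 = DW_ms(ReLU(IN(DilatedConv(x1))))                # large-receptive-field branch
    w1, w2 = sigmoid(Conv1x1(concat(x2, x3)))            # two spatial gate maps
    y  = x + PW_out(w1 * x2 + w2 * x3)

The two gate maps are independent sigmoids — unlike selective-kernel fusion
they are not constrained to sum to one.  Depthwise convolutions carry no
biases (the following pointwise layers have them); kernel sizes default to
5x5 on the gated path and 7x7 on the two multi-scale branches, with a dense
3x3 dilation-2 convolution opening the dilated branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn


@dataclass(frozen=True)
class MixConvParams:
    channels: int
    local_kernel: int = 5    # depthwise kernel on the gated path
    ms_kernel: int = 7       # depthwise kernel closing both multi-scale branches
    dilated_kernel: int = 3  # dense dilated convolution opening the second branch
    dilation: int = 2

    def __post_init__(self):
        for k in (self.local_kernel, self.ms_kernel, self.dilated_kernel):
            if k % 2 != 1:
                raise ValueError("kernel sizes must be odd")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")


class MixConvBlock(nn.Module):
    def __init__(self, p: MixConvParams, rng: np.random.Generator):
        super().__init__()
        C = p.channels
        self.p = p
        self.bn = nn.BatchNorm2d(C)
        self.pw_gate = nn.conv1x1(C, C, rng)
        self.pw_value = nn.conv1x1(C, C, rng)
        self.dw_local = nn.conv_same(C, C, p.local_kernel, rng, groups=C, bias=False)
        self.pw_branch = nn.conv1x1(C, C, rng)
        self.in_branch = nn.InstanceNorm2d(C)
        self.dw_branch = nn.conv_same(C, C, p.ms_kernel, rng, groups=C, bias=False)
        self.dconv = nn.conv_same(C, C, p.dilated_kernel, rng, dilation=p.dilation)
        self.in_dilated = nn.InstanceNorm2d(C)
        self.dw_dilated = nn.conv_same(C, C, p.ms_kernel, rng, groups=C, bias=False)
        self.gate_conv = nn.conv1x1(2 * C, 2, rng)
        self.proj = nn.conv1x1(C, C, rng)

    def gates(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """The two sigmoid gate maps for input ``x`` (each N x 1 x H x W)."""
        _, w1, w2 = self._paths(x)
        return w1, w2

    def _paths(self, x: nn.Tensor):
        C = self.p.channels
        if x.shape[1] != C:
            raise ValueError(f"expected {C} channels, got {x.shape[1]}")
        xb = self.bn(x)
        x1 = self.pw_gate(xb).sigmoid() * self.dw_local(self.pw_value(xb))
        x2 = self.dw_branch(self.in_branch(self.pw_branch(x1)).relu())
        x3 = self.dw_dilated(self.in_dilated(self.dconv(x1)).relu())
        w = self.gate_conv(nn.cat([x2, x3], axis=1)).sigmoid()
        return (x2, x3), w[:, 0:1], w[:, 1:2]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        (x2, x3), w1, w2 = self._paths(x)
        return x + self.proj(w1 * x2 + w2 * x3)


class GatedConvBlock(nn.Module):
    """Plain gated-convolution residual block (the ablation baseline block).

    BN -> [sigmoid(PW) * DW5(PW)] -> PW -> residual add.
    """

    def __init__(self, channels: int, rng: np.random.Generator, kernel: int = 5):
        super().__init__()
        C = channels
        self.channels = C
        self.bn = nn.BatchNorm2d(C)
        self.pw_gate = nn.conv1x1(C, C, rng)
        self.pw_value = nn.conv1x1(C, C, rng)
        self.dw = nn.conv_same(C, C, kernel, rng, groups=C, bias=False)
        self.proj = nn.conv1x1(C, C, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        xb = self.bn(x)
        out = self.pw_gate(xb).sigmoid() * self.dw(self.pw_value(xb))
        return x + self.proj(out)


def mixconv_param_count(p: MixConvParams) -> int:
    """Closed-form count of learnable scalars in one MixConv block."""
    C = p.channels
    count = 2 * C                                  # BatchNorm affine
    count += 4 * (C * C + C)                       # four pointwise convs with bias
    count += p.local_kernel**2 * C                 # depthwise, no bias
    count += 2 * p.ms_kernel**2 * C
    count += p.dilated_kernel**2 * C * C + C       # dense dilated conv with bias
    count += 2 * 2 * C                             # two InstanceNorm affines
    count += 2 * C * 2 + 2                         # gate conv: 2C -> 2 maps
    return count
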