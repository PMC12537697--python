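"""DUNet: U-shaped dehazing network with physics-informed skip processing.

Layout (4 feature scales by default)::

    stem 3->w0
    [blocks w0] --down--> [blocks w1] --down--> [blocks w2] --down--> [blocks w3]
        |skip                  |skip                 |skip               |
      1x1+DFEU             1x1+DFEU              1x1+DFEU             DFEU
        |                      |                     |                   |
    [blocks w0] <--SK+up-- [blocks w1] <--SK+up-- [blocks w2] <----up----'
    head w0->(K, B);  output = K * I - B + I     (gated global residual)

Stage blocks are MixConv blocks (or plain gated-convolution blocks for the
ablation baseline); one DFEU sits on every feature handed from the encoder
side to the decoder side, i.e. the three skip connections and the bottleneck.
Downsampling is a biasless 2x2 stride-2 convolution, upsampling a pointwise
convolution followed by 2x pixel shuffle.  Inputs are expected in [-1, 1]
with sides divisible by 2^(n_scales - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .blocks import (
    DFEU,
    DFEUParams,
    GatedConvBlock,
    MixConvBlock,
    MixConvParams,
    SKFusion,
)


@dataclass(frozen=True)
class ModelConfig:
    widths: tuple[int, ...] = (24, 48, 96, 192)
    depths: tuple[int, ...] = (2, 2, 2, 4)
    block: str = "mixconv"            # "mixconv" | "gated"
    use_dfeu: bool = True
    mixconv: dict = field(default_factory=dict)   # MixConvParams overrides
    dfeu: dict = field(default_factory=dict)      # DFEUParams overrides
    sk_reduction: int = 8
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.widths) != len(self.depths):
            raise ValueError("widths and depths must have equal length")
        if len(self.widths) < 2:
            raise ValueError("need at least two scales")
        if self.block not in ("mixconv", "gated"):
            raise ValueError(f"unknown block type {self.block!r}")

    @property
    def n_scales(self) -> int:
        return len(self.widths)

    @property
    def divisor(self) -> int:
        return 2 ** (self.n_scales - 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("widths", "depths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# canonical configurations of the ablation study
FULL = ModelConfig()
BASELINE = ModelConfig(block="gated", use_dfeu=False)
MIXCONV_ONLY = ModelConfig(block="mixconv", use_dfeu=False)
DFEU_ONLY = ModelConfig(block="gated", use_dfeu=True)

DESK_SCALE = ModelConfig(widths=(8, 16, 32, 64), depths=(1, 1, 1, 1))


class DUNet(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        w, d = config.widths, config.depths
        n = config.n_scales

        def make_stage(channels: int, depth: int) -> nn.Sequential:
            if config.block == "mixconv":
                blocks = [
                    MixConvBlock(MixConvParams(channels, **config.mixconv), rng)
                    for _ in range(depth)
                ]
            else:
                blocks = [GatedConvBlock(channels, rng) for _ in range(depth)]
            return nn.Sequential(*blocks)

        self.stem = nn.conv_same(config.in_channels, w[0], 3, rng)
        self.enc_stages = [make_stage(w[i], d[i]) for i in range(n - 1)]
        self.downs = [
            nn.Conv2d(w[i], w[i + 1], 2, rng, stride=2, bias=False)
            for i in range(n - 1)
        ]
        self.bottleneck = make_stage(w[-1], d[-1])
        self.skip_convs = [
            nn.conv1x1(w[i], w[i], rng, bias=False) for i in range(n - 1)
        ]
        if config.use_dfeu:
            self.dfeus = [
                DFEU(DFEUParams(w[i], **config.dfeu), rng) for i in range(n)
            ]
        else:
            self.dfeus = []
        self.ups = [
            nn.Sequential(nn.conv1x1(w[i + 1], 2 * w[i + 1], rng), nn.PixelShuffle(2))
            for i in reversed(range(n - 1))
        ]
        self.fusions = [
            SKFusion(w[i], rng, reduction=config.sk_reduction)
            for i in reversed(range(n - 1))
        ]
        self.dec_stages = [make_stage(w[i], d[i]) for i in reversed(range(n - 1))]
        self.head = nn.conv_same(w[0], config.in_channels + 1, 3, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n = self.config.n_scales
        _, c, h, w = x.shape
        div = self.config.divisor
        if h % div or w % div:
            raise ValueError(
                f"input sides must be divisible by {div}; got {h}x{w} "
                f"(pad the image to a multiple of {div})"
            )
        feat = self.stem(x)
        skips = []
        for i in range(n - 1):
            feat = self.enc_stages[i](feat)
            skips.append(self.skip_convs[i](feat))
            feat = self.downs[i](feat)
        feat = self.bottleneck(feat)
        if self.config.use_dfeu:
            skips = [self.dfeus[i](s) for i, s in enumerate(skips)]
            feat = self.dfeus[n - 1](feat)
        for j in range(n - 1):
            feat = self.ups[j](feat)
            feat = self.fusions[j](skips[n - 2 - j], feat)
            feat = self.dec_stages[j](feat)
        out = self.head(feat)
        k = out[:, 0:1]
        b = out[:, 1:]
        return k * x - b + x


def build_dunet(config: ModelConfig = FULL, seed: int | None = None) -> DUNet:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return DUNet(config, rng)


def count_parameters(model: DUNet, per_component: bool = False) -> dict:
    """Learnable-scalar counts, raw and in millions (4 decimals).

    With ``per_component=True`` the count is split into the architectural
    groups of the ablation study: stem/head, stage blocks, resampling and
    skip/fusion plumbing, and DFEU units.
    """
    total = model.n_parameters()
    out = {"total": total, "total_M": round(total / 1e6, 4)}
    if per_component:
        groups = {
            "stem_head": [model.stem, model.head],
            "blocks": model.enc_stages + [model.bottleneck] + model.dec_stages,
            "resampling": model.downs + model.ups,
            "skip_fusion": model.skip_convs + model.fusions,
            "dfeu": model.dfeus,
        }
        comp = {}
        for name, modules in groups.items():
            c = sum(m.n_parameters() for m in modules)
            comp[name] = {"count": c, "M": round(c / 1e6, 4)}
        out["components"] = comp
    return out


def ablation_parameter_table() -> dict:
    """Parameter totals and deltas of the four ablation configurations."""
    counts = {
        "baseline": build_dunet(BASELINE).n_parameters(),
        "mixconv_only": build_dunet(MIXCONV_ONLY).n_parameters(),
        "dfeu_only": build_dunet(DFEU_ONLY).n_parameters(),
        "full": build_dunet(FULL).n_parameters(),
    }
    deltas = {
        "mixconv": counts["mixconv_only"] - counts["baseline"],
        "dfeu": counts["dfeu_only"] - counts["baseline"],
        "combined": counts["full"] - counts["baseline"],
    }
    return {
        "counts": counts,
        "counts_M": {k: round(v / 1e6, 4) for k, v in counts.items()},
        "deltas": deltas,
        "deltas_M": {k: round(v / 1e6, 4) for k, v in deltas.items()},
    }


def save_checkpoint(model: DUNet, path: str) -> None:
    import json

    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str) -> DUNet:
    import json

    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    config = ModelConfig.from_dict(
        json.loads(state.pop("__config__").tobytes().decode())
    )
    model = build_dunet(config)
    model.load_state_dict(state)
    return model
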