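# Methods

## The degradation model

Haze is modelled by the atmospheric scattering model (ASM). A clear image
J degrades to the observed hazy image I through a per-pixel transmission
map t and a global atmospheric light A:

    I(x) = J(x) · t(x) + A · (1 − t(x)),        t(x) = e^(−β·d(x))

β is the atmospheric scattering coefficient and d the relative scene depth.
The model is algebraically invertible wherever t > 0:

    J(x) = (I(x) − A) / t(x) + A.

All images are processed as floats in [0, 1]; the conventional 8-bit
atmospheric light A = 170 becomes 170/255 ≈ 0.667. Synthesis defaults are
β = 2.0 and A = 170/255 — the standard operating point for paired
agricultural/remote-sensing haze data — and the dataset builder enforces
β ≤ 4 with d ≤ 1 so transmission never falls below e⁻⁴ ≈ 0.018 and pairs
remain invertible. The inversion itself refuses t below 10⁻³.

### Synthetic depth

Real pipelines obtain d from a monocular depth estimator. Here depth is a
Gaussian-smoothed white-noise field (kernel σ = 16 px by default), min-max
normalized to [0, 1]: it reproduces the statistical character the pipeline
needs — a smooth, spatially coherent relative-depth field — while being
fully seeded and self-contained. Whether a learned estimator's output should
be min-max normalized before the transmission formula is an open convention;
this generator assumes [0, 1] by construction.

### Splits

Train/val/test assignment follows the 7:1:2 rule with round-half-up on the
train and test shares and the remainder to validation; this is the unique
simple rounding rule under which 1978 pairs split into 1385/197/396. The
assignment is a seeded shuffle: identical seeds give identical manifests.

## The network

DUNet is a U-shaped encoder–decoder over four feature scales (default widths
24/48/96/192, depths 2/2/2/4, mirrored on the decoder side) with three
architectural ideas:

**MixConv block.** A residual block that batch-normalizes its input, applies
a sigmoid-gated pointwise/depthwise pair, then splits into a local branch
(pointwise → InstanceNorm → ReLU → 7×7 depthwise) and a large-receptive-field
branch (dense 3×3 dilation-2 convolution → InstanceNorm → ReLU → 7×7
depthwise). The two branch outputs are concatenated and a 1×1 convolution
with sigmoid produces two spatial gate maps w₁, w₂ that weight them before a
pointwise projection and the residual add. The gates are independent
sigmoids — deliberately *not* a softmax — so both branches can be fully on.

**DFEU (dehazing feature extraction unit).** Carries the ASM into feature
space. One branch estimates an atmospheric-light feature Ā through
3×3 conv → 1×11 and 11×1 depthwise strip convolutions (long-range context at
low parameter cost) → 3×3 conv → BatchNorm → ReLU → 1×1 conv → sigmoid; it is
fully convolutional, so Ā varies spatially rather than being a global scalar.
The other branch estimates a transmission feature t̄ from a 1/2/4 adaptive
average-pooling pyramid, bilinearly resized, concatenated (3C channels) and
squeezed through a pointwise bottleneck 3C → ⌊3C/2⌋ → C with a terminal
sigmoid. The dehazed feature is the exact feature-space inversion
J̄ = (Ī − Ā) / (t̄ + ε) + Ā with ε = 10⁻³ during learning (the sigmoid can
approach zero); ε = 0 is available and used by the exactness tests. One DFEU
sits on every feature handed from the encoder side to the decoder side: the
three skip connections and the bottleneck.

**SK fusion.** At each decoder junction the (DFEU-processed) skip feature and
the upsampled main-path feature are blended with per-channel softmax weights
derived from the global-average-pooled sum through a C → C/8 → 2C pointwise
MLP. Softmax over the two branches guarantees w₁ + w₂ = 1, making the output
a per-channel convex combination.

Downsampling is a biasless 2×2 stride-2 convolution; upsampling a pointwise
convolution followed by 2× pixel shuffle. The head produces four channels
interpreted as a gain map K and a bias map B, and the output is the gated
global residual K·I − B + I: with a zero-initialized head the network is
exactly the identity, so everything it learns is haze correction.

### Architecture reconstruction against published budgets

The stage widths, depths and several kernel conventions are not printed in
the literature this model family comes from; the published parameter totals
are the binding constraint. The configuration above was reconciled by exact
integer accounting so that

- baseline (gated blocks, no DFEU):   843,172  → 0.8432 M
- full model:                       4,192,464  → 4.1925 M
- combined substitution delta:      3,349,292  → 3.3493 M

all match the published figures at four decimals. The published *per-module*
deltas (+2.2371 M MixConv, +1.2328 M DFEU) are mutually inconsistent with the
published totals — they sum to 0.1206 M more than the published combined
delta — so no additive implementation can reproduce all five figures; this
implementation reproduces the three above exactly and reports its own exact
decomposition (+2.1140 M MixConv, +1.2353 M DFEU). Conventions fixed by the
budget rather than by taste: depthwise, downsampling and skip convolutions
are biasless; the gate convolution in MixConv maps 2C → 2 spatial maps; the
DFEU bottleneck is 3C → ⌊3C/2⌋ → C; the head has four channels (gated
residual) rather than three (plain addition).

## Training

L1 loss on [−1, 1]-normalized pairs (x′ = 2x − 1), AdamW with decoupled
weight decay 0.01, initial learning rate 2·10⁻⁴ and cosine decay to 1% of the
initial rate. The published phrase "decay factor 0.01" is ambiguous between
weight decay and learning-rate decay; both knobs exist, both default to the
canonical 0.01 reading, and both are exposed in the configuration.
Augmentation applies one shared random crop, a horizontal flip with
probability 0.5 and a rotation from {0°, 90°, 180°, 270°} to both images of a
pair — geometric transforms commute with the pixelwise ASM, so augmented
pairs still satisfy the compositing equation exactly. Center cropping is
used at validation/test time only. Checkpoint selection is by validation
PSNR.

### Desk scale

The reference schedule (batch 24, 1000 epochs, 256-crops on 1978 pairs of
512×512 images) is a GPU-scale computation and out of scope here. The
desk-scale configuration — widths 8/16/32/64 with depth 1 per stage, 20
synthetic 64×64 pairs, batch 4, 200 steps — runs in a few minutes on one CPU.
Its learning rate is 10⁻³ rather than 2·10⁻⁴: the schedule is three orders of
magnitude shorter than the reference one and the model three orders of
magnitude smaller, and the larger step size is the standard compensation.
At this scale the trained network gains roughly 8–11 dB of held-out PSNR over
the hazy input (the no-op baseline an untrained residual network would
produce), which demonstrates genuine learned dehazing but says nothing about
the absolute PSNR levels reachable with full-scale training on real imagery.

## Evaluation

PSNR = 10·log₁₀(max² / MSE) with MSE over all pixels and channels; identical
images produce an infinite-PSNR sentinel that is excluded from means and
counted separately. SSIM uses the standard 11×11 Gaussian window (σ = 1.5),
population covariance, k₁ = 0.01, k₂ = 0.03, computed per channel and
averaged; the implementation delegates the windowed statistics to
scikit-image, and closed-form cases (identity, constant images) in the test
suite pin the convention. Metrics are computed on RGB in [0, 1] with
max = L = 1; computing on 0–255 instead changes nothing (scale invariance is
tested to 10⁻⁹ dB). Whether published figures in this literature use RGB or
luminance is generally unstated; RGB is used here throughout.

## Numerical engine

No GPU framework is assumed: the network runs on a small reverse-mode
autodiff engine over numpy arrays (`dunet.nn`), implementing exactly the
operations the model needs — grouped/dilated/strided 2-D convolution,
batch/instance normalization, sigmoid/ReLU/softmax, adaptive average
pooling, bilinear resizing and pixel shuffle. Pooling and resizing are
expressed as separable spatial linear maps, which makes their adjoints exact
transposes; convolution gradients are computed by the standard
tap-enumeration formulas. Every operation is validated against central
finite differences (and convolution additionally against scipy correlation)
in the test suite. Computation is float32 for speed, fully deterministic,
and all randomness flows from explicit numpy generators, so equal seeds give
bitwise-equal models, training histories and reports.

## What the synthetic data does and does not show

The generator emulates the *construction* of paired haze data: smooth
depth-driven transmission, scalar atmospheric light, lossless storage. It
does not emulate real-scene content (its clear images are smoothed noise
with row structure, not rice paddies), non-homogeneous atmospheric light,
sensor noise, or the domain gap between synthetic and real haze. Passing
tests therefore certify the physics plumbing, the architecture and the
optimization loop — not field performance on real UAV imagery.

## Known limitations

- CPU-only: full-resolution (512×512) inference with the full model is slow;
  the engine is written for correctness and desk-scale sizes.
- BatchNorm statistics are per-run; very small batches make evaluation-mode
  behaviour sensitive to the training distribution.
- The ablation deltas are reported as the implementation computes them; the
  published per-module deltas cannot be matched simultaneously (see above).
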