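"""Layer zoo for the dehazing network.

Layers follow the usual container conventions: a :class:`Module` registers
parameters and sub-modules on attribute assignment, exposes
``named_parameters`` / ``state_dict`` and a train/eval switch that only
affects batch-norm statistics.  Construction is explicitly seeded: every layer
with weights draws them from the ``numpy`` ``Generator`` handed to its
constructor, so two models built from equal seeds are bitwise identical.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for key, (holder, attr) in self._all_buffers().items():
            state[key] = getattr(holder, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = self._all_buffers()
        for key, value in state.items():
            if key in own:
                if own[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                own[key].data = np.asarray(value, dtype=DTYPE)
            elif key in buffers:
                holder, attr = buffers[key]
                setattr(holder, attr, np.asarray(value))
            else:
                raise KeyError(f"unexpected key {key}")

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _all_buffers(self, prefix: str = ""):
        out = {}
        for k in self._buffers():
            out[prefix + k] = (self, k)
        for name, m in self._modules.items():
            out.update(m._all_buffers(prefix + name + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Conv2d(Module):
    """2-D convolution with 'same'-style padding left to the caller."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 rng: np.random.Generator, stride=1, padding=0, dilation=1,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.groups = groups
        fan_in = in_channels // groups * kh * kw
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_channels, in_channels // groups, kh, kw))
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        groups=self.groups)


def conv1x1(cin, cout, rng, bias=True):
    return Conv2d(cin, cout, 1, rng, bias=bias)


def conv_same(cin, cout, k, rng, dilation=1, groups=1, bias=True):
    """Odd-kernel convolution padded to preserve spatial shape."""
    kh, kw = (k, k) if isinstance(k, int) else k
    dh, dw = (dilation, dilation) if isinstance(dilation, int) else (dilation, dilation)
    return Conv2d(cin, cout, (kh, kw), rng, padding=(dh * (kh - 1) // 2, dw * (kw - 1) // 2),
                  dilation=dilation, groups=groups, bias=bias)


class _Norm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(num_features))
            self.beta = Parameter(np.zeros(num_features))

    def _affine(self, xhat: Tensor) -> Tensor:
        if not self.affine:
            return xhat
        shape = (1, self.num_features, 1, 1)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm2d(_Norm2d):
    """Batch normalization over (N, H, W) with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(num_features, eps)
        self.momentum_ = momentum
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / self.num_features
            self.running_mean = (
                (1 - self.momentum_) * self.running_mean
                + self.momentum_ * mu.data.reshape(-1).astype(DTYPE)
            )
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = (
                (1 - self.momentum_) * self.running_var
                + self.momentum_ * unbiased.astype(DTYPE)
            )
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            shape = (1, self.num_features, 1, 1)
            mu = self.running_mean.reshape(shape)
            var = self.running_var.reshape(shape)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return self._affine(xhat)


class InstanceNorm2d(_Norm2d):
    """Per-sample, per-channel normalization; no running statistics."""

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return self._affine(xhat)


class PixelShuffle(Module):
    """Rearrange (N, C*r^2, H, W) -> (N, C, H*r, W*r)."""

    def __init__(self, upscale: int):
        super().__init__()
        self.r = upscale

    def forward(self, x: Tensor) -> Tensor:
        n, crr, h, w = x.shape
        r = self.r
        c = crr // (r * r)
        y = x.reshape(n, c, r, r, h, w)
        y = y.transpose((0, 1, 4, 2, 5, 3))
        return y.reshape(n, c, h * r, w * r)


# ---------------------------------------------------------------------------
# functional spatial resamplers built on Tensor.spatial_map


def _adaptive_matrix(n_in: int, n_out: int) -> np.ndarray:
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def adaptive_avg_pool2d(x: Tensor, output_size: int) -> Tensor:
    """Average-pool to an ``output_size`` x ``output_size`` grid."""
    _, _, h, w = x.shape
    return x.spatial_map(_adaptive_matrix(h, output_size).astype(x.data.dtype),
                         _adaptive_matrix(w, output_size).astype(x.data.dtype))


def global_avg_pool(x: Tensor) -> Tensor:
    return adaptive_avg_pool2d(x, 1)


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Half-pixel-centre (align_corners=False) interpolation matrix."""
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    _, _, h, w = x.shape
    return x.spatial_map(_bilinear_matrix(h, size[0]).astype(x.data.dtype),
                         _bilinear_matrix(w, size[1]).astype(x.data.dtype))


def softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
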