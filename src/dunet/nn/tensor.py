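"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and records
the closure needed to push gradients back to its inputs.  Only the operations
used by the dehazing network are implemented — elementwise arithmetic with
broadcasting, activations, reductions, reshaping, concatenation/slicing, 2-D
convolution (with stride, dilation and groups) and separable spatial linear
maps (which cover bilinear resizing, adaptive average pooling and global
average pooling).

Gradients accumulate in ``Tensor.grad`` after calling :meth:`Tensor.backward`
on a scalar.  Everything is deterministic: no op consumes global random state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None  # free graph
                node._parents = ()

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(out_data, (self,), backward)

    # -- activations ----------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._from_op(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            self._accumulate(g * e)

        return Tensor._from_op(e, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return Tensor._from_op(np.abs(self.data), (self,), backward)

    def sqrt(self):
        r = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / r)

        return Tensor._from_op(r, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._from_op(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor._from_op(out_data, (self,), backward)

    def pad2d(self, ph: int, pw: int):
        """Zero-pad the two trailing (spatial) axes symmetrically."""
        if ph == 0 and pw == 0:
            return self
        pads = [(0, 0)] * (self.ndim - 2) + [(ph, ph), (pw, pw)]
        out_data = np.pad(self.data, pads)
        sl = (Ellipsis, slice(ph, ph + self.shape[-2]), slice(pw, pw + self.shape[-1]))

        def backward(g):
            self._accumulate(g[sl])

        return Tensor._from_op(out_data, (self,), backward)

    # -- spatial linear map ---------------------------------------------------
    def spatial_map(self, row: np.ndarray, col: np.ndarray):
        """``out[..., i, j] = sum_{h,w} row[i,h] * col[j,w] * x[..., h, w]``.

        With suitable matrices this implements average pooling, adaptive
        pooling and bilinear resizing, all with an exact transpose backward.
        """

        def apply(x, r, c):
            # contract h with r, then w with c
            t = np.tensordot(x, r, axes=([-2], [1]))   # (..., w, i)
            t = np.tensordot(t, c, axes=([-2], [1]))   # (..., i, j)
            return np.ascontiguousarray(t)

        out_data = apply(self.data, row, col)

        def backward(g):
            self._accumulate(apply(g, row.T, col.T))

        return Tensor._from_op(out_data, (self,), backward)

    # -- convolution ----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride=1, padding=0, dilation=1, groups: int = 1):
        sh, sw = (stride, stride) if isinstance(stride, int) else stride
        ph, pw = (padding, padding) if isinstance(padding, int) else padding
        dh, dw = (dilation, dilation) if isinstance(dilation, int) else dilation
        x = self.pad2d(ph, pw)
        n, cin, h, w = x.shape
        cout, cg, kh, kw = weight.shape
        if cin != cg * groups:
            raise ValueError(
                f"conv2d: input has {cin} channels, weight expects {cg * groups}"
            )
        ho = (h - dh * (kh - 1) - 1) // sh + 1
        wo = (w - dw * (kw - 1) - 1) // sw + 1
        if ho <= 0 or wo <= 0:
            raise ValueError("conv2d: spatial dims too small for kernel")
        taps = []
        for i in range(kh):
            for j in range(kw):
                rs = slice(i * dh, i * dh + (ho - 1) * sh + 1, sh)
                cs = slice(j * dw, j * dw + (wo - 1) * sw + 1, sw)
                taps.append((i, j, rs, cs))

        depthwise = groups == cin and cg == 1 and cout == cin
        wd = weight.data
        if depthwise:
            # out[n,c] = sum_ij x[n,c,rs,cs] * w[c,0,i,j]
            out = np.zeros((n, cout, ho, wo), dtype=x.data.dtype)
            for i, j, rs, cs in taps:
                out += x.data[:, :, rs, cs] * wd[:, 0, i, j][:, None, None]
        elif groups == 1:
            if kh == kw == 1 and sh == sw == 1:
                # pointwise: a single matmul over flattened space
                out = np.matmul(wd.reshape(cout, cin),
                                x.data.reshape(n, cin, h * w)).reshape(n, cout, ho, wo)
            else:
                out = np.zeros((n, cout, ho * wo), dtype=x.data.dtype)
                for i, j, rs, cs in taps:
                    out += np.matmul(wd[:, :, i, j],
                                     x.data[:, :, rs, cs].reshape(n, cin, -1))
                out = out.reshape(n, cout, ho, wo)
        else:
            og = cout // groups
            xg = x.data.reshape(n, groups, cg, h, w)
            wg = wd.reshape(groups, og, cg, kh, kw)
            out = np.zeros((n, groups, og, ho, wo), dtype=x.data.dtype)
            for i, j, rs, cs in taps:
                out += np.einsum("ngchw,goc->ngohw", xg[:, :, :, rs, cs],
                                 wg[:, :, :, i, j], optimize=True)
            out = out.reshape(n, cout, ho, wo)
        if bias is not None:
            out += bias.data.reshape(1, cout, 1, 1)

        parents = (x, weight) if bias is None else (x, weight, bias)

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if depthwise:
                if weight.requires_grad:
                    dw_ = np.empty_like(wd)
                    for i, j, rs, cs in taps:
                        dw_[:, 0, i, j] = np.sum(g * x.data[:, :, rs, cs],
                                                 axis=(0, 2, 3))
                    weight._accumulate(dw_)
                if x.requires_grad:
                    dx = np.zeros((n, cin, h, w), dtype=x.data.dtype)
                    for i, j, rs, cs in taps:
                        dx[:, :, rs, cs] += g * wd[:, 0, i, j][:, None, None]
                    x._accumulate(dx)
            elif groups == 1:
                gflat = g.reshape(n, cout, ho * wo)
                if weight.requires_grad:
                    dw_ = np.zeros_like(wd)
                    for i, j, rs, cs in taps:
                        xs = x.data[:, :, rs, cs].reshape(n, cin, -1)
                        dw_[:, :, i, j] = np.matmul(
                            gflat, xs.transpose(0, 2, 1)
                        ).sum(axis=0)
                    weight._accumulate(dw_)
                if x.requires_grad:
                    dx = np.zeros((n, cin, h, w), dtype=x.data.dtype)
                    for i, j, rs, cs in taps:
                        dx[:, :, rs, cs] += np.matmul(
                            wd[:, :, i, j].T, gflat
                        ).reshape(n, cin, ho, wo)
                    x._accumulate(dx)
            else:
                og = cout // groups
                xg = x.data.reshape(n, groups, cg, h, w)
                wg = wd.reshape(groups, og, cg, kh, kw)
                gg = g.reshape(n, groups, og, ho, wo)
                if weight.requires_grad:
                    dw_ = np.empty_like(wg)
                    for i, j, rs, cs in taps:
                        dw_[:, :, :, i, j] = np.einsum(
                            "ngohw,ngchw->goc", gg, xg[:, :, :, rs, cs],
                            optimize=True)
                    weight._accumulate(dw_.reshape(weight.shape))
                if x.requires_grad:
                    dx = np.zeros((n, groups, cg, h, w), dtype=x.data.dtype)
                    for i, j, rs, cs in taps:
                        dx[:, :, :, rs, cs] += np.einsum(
                            "ngohw,goc->ngchw", gg, wg[:, :, :, i, j],
                            optimize=True)
                    x._accumulate(dx.reshape(n, cin, h, w))

        return Tensor._from_op(out, parents, backward)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)
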