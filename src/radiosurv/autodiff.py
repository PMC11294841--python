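"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the survival architectures need: dense
algebra with broadcasting, element-wise nonlinearities, softmax /
log-sum-exp with detached max-shifts, 2-D convolution, non-overlapping
transposed convolution (kernel == stride, the classic U-Net up-conv),
2x2 max pooling, concatenation and slicing. Gradients are accumulated
by a topological backward sweep from a scalar (or any seeded) output.

The engine is deliberately small: correctness is guarded by numerical
gradient checks in the test suite rather than by generality.
"""

from __future__ import annotations

import numpy as np


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(),
                 _backward=None, name: str | None = None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, seed=None):
        """Backpropagate from this tensor (scalar unless ``seed`` given)."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar")
            seed = np.ones_like(self.data)
        self._accum(np.asarray(seed, dtype=float))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_sum_to_shape(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_sum_to_shape(gb, other.data.shape))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    # -- element-wise --------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))
        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))
        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))
        out._backward = bw
        return out

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _prev=(self,))

        def bw(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes) if axes
                     else self.data.T, _prev=(self,))
        inv = np.argsort(axes) if axes else None

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv) if inv is not None else g.T)
        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift treated as a constant)."""
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    out = (x - shift).exp().sum(axis=axis, keepdims=True).log() + shift
    if not keepdims and axis is not None:
        sq = out.data.squeeze(axis)
        out = out.reshape(sq.shape)
    elif not keepdims and axis is None:
        out = out.reshape(())
    return out


# ---------------------------------------------------------------------------
# spatial operations
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; x: (N,C,H,W), w: (Co,C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    view = np.lib.stride_tricks.sliding_window_view(
        xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = np.einsum("nchwij,ocij->nohw", view, w.data, optimize=True)
    prev = (x, w) if b is None else (x, w, b)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        prev = (x, w, b)
    out = Tensor(out_data, _prev=prev)
    Ho, Wo = out_data.shape[2:]

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nohw->ocij", view, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            if padding:
                gxp = gxp[:, :, padding:padding + H, padding:padding + W]
            x._accum(gxp)
    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     scale: int = 2) -> Tensor:
    """Non-overlapping transposed convolution (kernel size == stride).

    x: (N,C,H,W), w: (C,Co,k,k) with k == scale; output (N,Co,H*k,W*k).
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Ci, Co, k, k2 = w.shape
    if Ci != C or k != scale or k2 != scale:
        raise ValueError("conv_transpose2d expects kernel (C,Co,scale,scale)")
    tmp = np.einsum("nchw,coab->nohwab", x.data, w.data, optimize=True)
    out_data = tmp.transpose(0, 1, 2, 4, 3, 5).reshape(N, Co, H * k, W * k)
    prev = (x, w)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        prev = (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        gtmp = g.reshape(N, Co, H, k, W, k).transpose(0, 1, 2, 4, 3, 5)
        if x.requires_grad:
            x._accum(np.einsum("nohwab,coab->nchw", gtmp, w.data,
                               optimize=True))
        if w.requires_grad:
            w._accum(np.einsum("nchw,nohwab->coab", x.data, gtmp,
                               optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
    out._backward = bw
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError("maxpool2d requires dimensions divisible by k")
    view = x.data.reshape(N, C, H // k, k, W // k, k)
    out_data = view.max(axis=(3, 5))
    out = Tensor(out_data, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            exp = out_data[:, :, :, None, :, None]
            mask = (view == exp)
            counts = mask.sum(axis=(3, 5), keepdims=True)
            gv = mask * (g[:, :, :, None, :, None] / counts)
            x._accum(gv.reshape(N, C, H, W))
    out._backward = bw
    return out
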