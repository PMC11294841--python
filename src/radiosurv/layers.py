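"""Neural building blocks on top of the autodiff engine.

Includes the pathway-masked sparse layer, scaled-dot / multi-head
attention (both numpy-facing functions and trainable modules), standard
dense/conv layers and the Adam optimizer with post-step constraint
hooks (used to re-project masked weights to exact zero).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor, concat, conv2d, conv_transpose2d, softmax
from .datatypes import PathwayMask

_ACTS = {
    None: lambda t: t,
    "linear": lambda t: t,
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
}


class Module:
    """Lightweight parameter container; children found via attributes."""

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def constraints(self) -> list:
        """Post-step constraint callables, collected recursively."""
        hooks = []

        def walk(obj):
            if isinstance(obj, Module):
                own = getattr(obj, "_constraint", None)
                if own is not None:
                    hooks.append(own)
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return hooks

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=float)


def _glorot(rng, fan_in, fan_out, shape):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng, activation=None,
                 bias_init: float = 0.0):
        self.W = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.full(n_out, float(bias_init)), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        return _ACTS[self.activation](as_tensor(x) @ self.W + self.b)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, rng, kernel: int = 3,
                 stride: int = 1, padding: int = 1, activation=None,
                 bias_init: float = 0.0):
        fan_in = c_in * kernel * kernel
        self.W = Tensor(_glorot(rng, fan_in, c_out, (c_out, c_in, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.full(c_out, float(bias_init)), requires_grad=True)
        self.stride, self.padding = stride, padding
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.W, self.b, stride=self.stride,
                     padding=self.padding)
        return _ACTS[self.activation](out)


class ConvTranspose2d(Module):
    """Up-convolution with kernel == stride (non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, rng, scale: int = 2,
                 activation=None):
        fan_in = c_in
        self.W = Tensor(_glorot(rng, fan_in, c_out * scale * scale,
                                (c_in, c_out, scale, scale)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.scale = scale
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = conv_transpose2d(x, self.W, self.b, scale=self.scale)
        return _ACTS[self.activation](out)


# ---------------------------------------------------------------------------
# pathway-masked sparse layer
# ---------------------------------------------------------------------------

def apply_mask_constraint(W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Project a weight matrix onto the mask support: ``W * A``."""
    W, A = np.asarray(W), np.asarray(A)
    if W.shape != A.shape:
        raise ValueError(f"weight shape {W.shape} != mask shape {A.shape}")
    return W * A


class SparsePathwayLayer(Module):
    """Gene layer followed by a pathway layer with masked connections.

    Forward pass: ``relu((W * A)^T relu(W0^T g0 + b0) + b)`` where A is
    the binary gene x pathway membership mask. The stored pathway weight
    W is re-projected onto the mask support after every optimizer step
    (the forward multiplies by A regardless, so outputs never depend on
    masked entries).
    """

    def __init__(self, mask: PathwayMask | np.ndarray, rng,
                 diagonal_gene_layer: bool = False):
        A = mask.matrix if isinstance(mask, PathwayMask) else np.asarray(mask)
        m, q = A.shape
        self.A = Tensor(A.astype(float))
        self.diagonal = diagonal_gene_layer
        if diagonal_gene_layer:
            self.W0 = Tensor(np.ones(m), requires_grad=True)
        else:
            self.W0 = Tensor(_glorot(rng, m, m, (m, m)), requires_grad=True)
        # small positive bias keeps the ReLU units initially alive
        self.b0 = Tensor(np.full(m, 0.1), requires_grad=True)
        self.W = Tensor(apply_mask_constraint(
            _glorot(rng, m, q, (m, q)), A), requires_grad=True)
        self.b = Tensor(np.full(q, 0.1), requires_grad=True)

    def _constraint(self):
        self.W.data = apply_mask_constraint(self.W.data, self.A.data)

    def __call__(self, g0: Tensor) -> Tensor:
        g0 = as_tensor(g0)
        if self.diagonal:
            hidden = (g0 * self.W0 + self.b0).relu()
        else:
            hidden = (g0 @ self.W0 + self.b0).relu()
        return (hidden @ (self.W * self.A) + self.b).relu()


class MaskedDense(Module):
    """Dense layer whose weight is element-wise masked (decoder mirror)."""

    def __init__(self, mask_T: np.ndarray, rng, activation=None):
        q, m = np.asarray(mask_T).shape
        self.A = Tensor(np.asarray(mask_T, dtype=float))
        self.W = Tensor(apply_mask_constraint(
            _glorot(rng, q, m, (q, m)), self.A.data), requires_grad=True)
        self.b = Tensor(np.zeros(m), requires_grad=True)
        self.activation = activation

    def _constraint(self):
        self.W.data = apply_mask_constraint(self.W.data, self.A.data)

    def __call__(self, x: Tensor) -> Tensor:
        return _ACTS[self.activation](as_tensor(x) @ (self.W * self.A) + self.b)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def scaled_dot_attention_t(Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V on (tokens x dim) tensors."""
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("query/key dimension mismatch")
    d_k = Q.shape[-1]
    scores = (Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)
              if K.ndim > 2 else Q @ K.T) * (1.0 / np.sqrt(d_k))
    return softmax(scores, axis=-1) @ V


def scaled_dot_attention(Q, K, V) -> np.ndarray:
    """Numpy-facing scaled dot-product attention."""
    return scaled_dot_attention_t(Tensor(Q), Tensor(K), Tensor(V)).data


class MultiHeadAttention(Module):
    """Multi-head attention with per-head Q/K/V projections and output
    projection W^O. Cross-attention = queries from one modality, keys
    and values from the other."""

    def __init__(self, dim: int, n_heads: int, rng, key_dim: int | None = None):
        if n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        self.n_heads = n_heads
        self.key_dim = key_dim or max(1, dim // n_heads)
        d_k = self.key_dim
        self.Wq = [Tensor(_glorot(rng, dim, d_k, (dim, d_k)), requires_grad=True)
                   for _ in range(n_heads)]
        self.Wk = [Tensor(_glorot(rng, dim, d_k, (dim, d_k)), requires_grad=True)
                   for _ in range(n_heads)]
        self.Wv = [Tensor(_glorot(rng, dim, d_k, (dim, d_k)), requires_grad=True)
                   for _ in range(n_heads)]
        self.Wo = Tensor(_glorot(rng, n_heads * d_k, dim,
                                 (n_heads * d_k, dim)), requires_grad=True)

    def __call__(self, Q_in: Tensor, K_in: Tensor, V_in: Tensor) -> Tensor:
        Q_in, K_in, V_in = as_tensor(Q_in), as_tensor(K_in), as_tensor(V_in)
        heads = [scaled_dot_attention_t(Q_in @ wq, K_in @ wk, V_in @ wv)
                 for wq, wk, wv in zip(self.Wq, self.Wk, self.Wv)]
        return concat(heads, axis=-1) @ self.Wo


def multi_head_attention(Q_in, K_in, V_in, Wq, Wk, Wv, Wo) -> np.ndarray:
    """Numpy-facing multi-head attention with explicit projection lists."""
    heads = [scaled_dot_attention(np.asarray(Q_in) @ wq,
                                  np.asarray(K_in) @ wk,
                                  np.asarray(V_in) @ wv)
             for wq, wk, wv in zip(Wq, Wk, Wv)]
    return np.concatenate(heads, axis=-1) @ np.asarray(Wo)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with optional exponential learning-rate decay and post-step
    constraint hooks (mask re-projection)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, lr_decay: float = 1.0,
                 constraints=()):
        self.params = list(params)
        self.lr0, self.lr_decay = lr, lr_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
        self.constraints = list(constraints)

    @property
    def lr(self) -> float:
        return self.lr0 * self.lr_decay ** self.t

    def step(self):
        self.t += 1
        lr = self.lr0 * self.lr_decay ** (self.t - 1)
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
        for hook in self.constraints:
            hook()

    def zero_grad(self):
        for p in self.params:
            p.grad = None
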