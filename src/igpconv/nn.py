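"""A small NumPy layer toolkit with reverse-mode automatic differentiation.

Provides exactly the operations needed by the substituted classifier:
1x1 (pointwise) and grouped pointwise convolutions, spatial and depthwise
convolutions with TensorFlow-style "same" padding, batch normalisation,
global average pooling, dense heads, swish/relu/sigmoid, dropout and a
fused softmax cross-entropy — each with a hand-written backward pass.
Tensors are plain ``numpy`` arrays wrapped in a tape node; calling
``backward()`` on a scalar loss walks the tape in reverse topological
order.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module",
    "swish", "relu", "sigmoid", "add", "mul", "concat_channels",
    "gather_channels", "global_avg_pool", "dropout",
    "softmax_cross_entropy", "softmax",
    "Conv2D", "DepthwiseConv2D", "PointwiseConv", "GroupedPointwise",
    "BatchNorm", "Dense", "RMSProp", "glorot_uniform",
]


class Tensor:
    """A tape node: array data plus the closure that propagates gradients."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad=False, parents=(), bwd=None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._bwd: Optional[Callable[[np.ndarray], None]] = bwd

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal container: collects parameters from attributes recursively."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: list, seen: set) -> None:
        for v in vars(self).values():
            self._collect_value(v, out, seen)

    @staticmethod
    def _collect_value(v, out, seen) -> None:
        if isinstance(v, Parameter):
            if id(v) not in seen:
                seen.add(id(v))
                out.append(v)
        elif isinstance(v, Module):
            v._collect(out, seen)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect_value(item, out, seen)

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes introduced or broadcast by numpy rules."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._bwd = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._bwd = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._bwd = bwd
    return out


def swish(x: Tensor, beta: float = 1.0) -> Tensor:
    """x * sigmoid(beta * x); beta fixed (non-trainable)."""
    s = 1.0 / (1.0 + np.exp(-beta * x.data))
    out = Tensor(x.data * s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (s + beta * x.data * s * (1.0 - s)))

    out._bwd = bwd
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._bwd = bwd
    return out


def gather_channels(x: Tensor, idx: Sequence[int]) -> Tensor:
    """Select (possibly repeating) channels along the last axis; the
    backward pass scatter-adds, so replicated channels accumulate."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[..., idx], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, (..., idx), g)
            x._accumulate(gx)

    out._bwd = bwd
    return out


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1),
                 parents=tuple(tensors))
    sizes = [t.data.shape[-1] for t in tensors]

    def bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(g[..., start:start + s])
            start += s

    out._bwd = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """N×H×W×C -> N×C mean over the spatial axes."""
    n, h, w, c = x.data.shape
    out = Tensor(x.data.mean(axis=(1, 2)), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, None, None, :] / (h * w),
                                          x.data.shape))

    out._bwd = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._bwd = bwd
    return out


def tensor_sum(x: Tensor) -> Tensor:
    out = Tensor(np.asarray(x.data.sum()), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g, x.data.shape))

    out._bwd = bwd
    return out


def reshape(x: Tensor, shape: tuple) -> Tensor:
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    out._bwd = bwd
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, probabilities)."""
    p = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    loss_val = -np.log(p[np.arange(n), labels] + eps).mean()
    out = Tensor(np.asarray(loss_val, dtype=logits.data.dtype), parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            gl = p.copy()
            gl[np.arange(n), labels] -= 1.0
            logits._accumulate(g * gl / n)

    out._bwd = bwd
    return out, p


def glorot_uniform(rng: np.random.Generator, shape: tuple,
                   fan_in: int, fan_out: int, dtype=np.float32) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _same_pad(in_size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-in_size // s)
    total = max((out - 1) * s + k - in_size, 0)
    return total // 2, total - total // 2


def _patches(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N, Ho, Wo, k, k, C) strided view."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # v: (N, Hp-k+1, Wp-k+1, C, k, k) -> subsample stride, reorder axes
    v = v[:, ::s, ::s]
    return np.moveaxis(v, 3, 5)


class Conv2D(Module):
    """Spatial convolution (NHWC), TF-style same padding, optional bias."""

    def __init__(self, rng, in_ch: int, filters: int, kernel: int,
                 stride: int = 1, use_bias: bool = False):
        self.kernel, self.stride, self.in_ch, self.filters = kernel, stride, in_ch, filters
        fan_in = kernel * kernel * in_ch
        self.w = Parameter(glorot_uniform(rng, (filters, kernel, kernel, in_ch),
                                          fan_in, filters))
        self.b = Parameter(np.zeros(filters, dtype=np.float32)) if use_bias else None

    def __call__(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        n, h, wd, c = x.data.shape
        ph = _same_pad(h, k, s)
        pw = _same_pad(wd, k, s)
        xp = np.pad(x.data, ((0, 0), ph, pw, (0, 0)))
        pat = _patches(xp, k, s)
        y = np.einsum("nhwklc,fklc->nhwf", pat, self.w.data, optimize=True)
        if self.b is not None:
            y = y + self.b.data
        parents = (x, self.w) + ((self.b,) if self.b is not None else ())
        out = Tensor(y, parents=parents)
        ho, wo = y.shape[1], y.shape[2]

        def bwd(g):
            if self.w.requires_grad:
                self.w._accumulate(np.einsum("nhwf,nhwklc->fklc", g, pat,
                                             optimize=True))
            if self.b is not None:
                self.b._accumulate(g.sum(axis=(0, 1, 2)))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for ki in range(k):
                    for kj in range(k):
                        gxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += np.einsum(
                            "nhwf,fc->nhwc", g, self.w.data[:, ki, kj, :],
                            optimize=True)
                x._accumulate(gxp[:, ph[0]:ph[0] + h, pw[0]:pw[0] + wd, :])

        out._bwd = bwd
        return out


class DepthwiseConv2D(Module):
    """Per-channel spatial convolution (depth multiplier 1)."""

    def __init__(self, rng, in_ch: int, kernel: int, stride: int = 1):
        self.kernel, self.stride, self.in_ch = kernel, stride, in_ch
        fan = kernel * kernel
        self.w = Parameter(glorot_uniform(rng, (kernel, kernel, in_ch), fan, fan))

    def __call__(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        n, h, wd, c = x.data.shape
        ph = _same_pad(h, k, s)
        pw = _same_pad(wd, k, s)
        xp = np.pad(x.data, ((0, 0), ph, pw, (0, 0)))
        pat = _patches(xp, k, s)
        y = np.einsum("nhwklc,klc->nhwc", pat, self.w.data, optimize=True)
        out = Tensor(y, parents=(x, self.w))
        ho, wo = y.shape[1], y.shape[2]

        def bwd(g):
            if self.w.requires_grad:
                self.w._accumulate(np.einsum("nhwc,nhwklc->klc", g, pat,
                                             optimize=True))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for ki in range(k):
                    for kj in range(k):
                        gxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += (
                            g * self.w.data[ki, kj, :])
                x._accumulate(gxp[:, ph[0]:ph[0] + h, pw[0]:pw[0] + wd, :])

        out._bwd = bwd
        return out


class PointwiseConv(Module):
    """Standard 1x1 convolution: an F×C weight matrix applied per position."""

    def __init__(self, rng, in_ch: int, filters: int, use_bias: bool = False):
        self.in_ch, self.filters = in_ch, filters
        self.w = Parameter(glorot_uniform(rng, (filters, in_ch), in_ch, filters))
        self.b = Parameter(np.zeros(filters, dtype=np.float32)) if use_bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x.data @ self.w.data.T
        if self.b is not None:
            y = y + self.b.data
        parents = (x, self.w) + ((self.b,) if self.b is not None else ())
        out = Tensor(y, parents=parents)

        def bwd(g):
            if self.w.requires_grad:
                gf = g.reshape(-1, g.shape[-1])
                xf = x.data.reshape(-1, x.data.shape[-1])
                self.w._accumulate(gf.T @ xf)
            if self.b is not None:
                self.b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
            if x.requires_grad:
                x._accumulate(g @ self.w.data)

        out._bwd = bwd
        return out


class GroupedPointwise(Module):
    """One grouped path: G groups of Fg filters, each filter seeing the
    ``width`` channels listed in its group's index row (replication =
    repeated indices).  Output is the group-major concatenation, G*Fg
    channels."""

    def __init__(self, rng, input_groups: Sequence[Sequence[int]],
                 filters_per_group: int, use_bias: bool = False):
        self.idx = np.asarray([list(g) for g in input_groups], dtype=np.intp)
        g, width = self.idx.shape
        self.groups, self.fpg, self.width = g, filters_per_group, width
        self.w = Parameter(glorot_uniform(rng, (g, filters_per_group, width),
                                          width, filters_per_group))
        self.b = (Parameter(np.zeros(g * filters_per_group, dtype=np.float32))
                  if use_bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        xg = x.data[..., self.idx]                     # (..., G, width)
        y = np.einsum("nhwgc,gfc->nhwgf", xg, self.w.data, optimize=True)
        y = y.reshape(y.shape[:3] + (self.groups * self.fpg,))
        if self.b is not None:
            y = y + self.b.data
        parents = (x, self.w) + ((self.b,) if self.b is not None else ())
        out = Tensor(y, parents=parents)

        def bwd(g_):
            gg = g_.reshape(g_.shape[:3] + (self.groups, self.fpg))
            if self.w.requires_grad:
                self.w._accumulate(np.einsum("nhwgf,nhwgc->gfc", gg, xg,
                                             optimize=True))
            if self.b is not None:
                self.b._accumulate(g_.reshape(-1, g_.shape[-1]).sum(axis=0))
            if x.requires_grad:
                gxg = np.einsum("nhwgf,gfc->nhwgc", gg, self.w.data,
                                optimize=True)
                gx = np.zeros_like(x.data)
                np.add.at(gx, (..., self.idx), gxg)
                x._accumulate(gx)

        out._bwd = bwd
        return out

    def set_weights(self, per_group: Sequence[np.ndarray]) -> None:
        """Load weights given as one (Fg, width) matrix per group."""
        self.w.data = np.stack([np.asarray(w, dtype=self.w.data.dtype)
                                for w in per_group])

    def get_weights(self) -> list[np.ndarray]:
        return [self.w.data[m] for m in range(self.groups)]


class BatchNorm(Module):
    """Channel-wise batch normalisation with trainable scale/offset and
    running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        y = self.gamma.data * xhat + self.beta.data
        out = Tensor(y, parents=(x, self.gamma, self.beta))
        m = x.data.size // x.data.shape[-1]

        def bwd(g):
            if self.gamma.requires_grad:
                self.gamma._accumulate((g * xhat).sum(axis=axes))
            if self.beta.requires_grad:
                self.beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                if training:
                    gx = (self.gamma.data * inv / m) * (
                        m * g
                        - g.sum(axis=axes)
                        - xhat * (g * xhat).sum(axis=axes))
                else:
                    gx = g * self.gamma.data * inv
                x._accumulate(gx)

        out._bwd = bwd
        return out


class Dense(Module):
    def __init__(self, rng, in_features: int, out_features: int,
                 use_bias: bool = True):
        self.w = Parameter(glorot_uniform(rng, (out_features, in_features),
                                          in_features, out_features))
        self.b = (Parameter(np.zeros(out_features, dtype=np.float32))
                  if use_bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        y = x.data @ self.w.data.T
        if self.b is not None:
            y = y + self.b.data
        parents = (x, self.w) + ((self.b,) if self.b is not None else ())
        out = Tensor(y, parents=parents)

        def bwd(g):
            if self.w.requires_grad:
                self.w._accumulate(g.T @ x.data)
            if self.b is not None:
                self.b._accumulate(g.sum(axis=0))
            if x.requires_grad:
                x._accumulate(g @ self.w.data)

        out._bwd = bwd
        return out


class RMSProp:
    """RMSProp with the usual leaky average of squared gradients."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 rho: float = 0.9, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
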