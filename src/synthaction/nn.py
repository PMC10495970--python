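"""Minimal reverse-mode autodiff and neural-network core on numpy.

The trainable models in this package (recurrent classifiers and
sequence-to-sequence converters) run on this small engine: float32 tensors,
a tape built by operator closures, topological-order backpropagation, fused
cells for LSTM/GRU steps and the attention/softmax/cross-entropy hot paths,
and the standard first-order optimizers (SGD, RMSprop, Adam, Adamax, Nadam).

Design notes:

* shapes follow the usual conventions — matmul supports stacked (batched)
  operands with identical leading dimensions; elementwise ops broadcast and
  gradients are summed back to the parent shape;
* all computation is single-threaded numpy, so runs are bitwise reproducible
  for a fixed seed;
* `no_grad()` disables tape construction for inference/decoding loops.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor", "no_grad", "Parameter",
    "Linear", "Embedding", "LayerNorm", "Dropout",
    "LSTMCell", "GRUCell", "MultiHeadAttention",
    "softmax", "cross_entropy_logits", "bce_logits",
    "sinusoidal_positions", "clip_grad_norm", "make_optimizer",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_back")

    def __init__(self, data, parents: tuple = (), back: Optional[Callable] = None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float32)
        if self.data.dtype != np.float32:
            self.data = self.data.astype(np.float32)
        self.grad: Optional[np.ndarray] = None
        self._parents = parents if _GRAD_ENABLED else ()
        self._back = back if _GRAD_ENABLED else None

    # -- graph ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._back is not None and node.grad is not None:
                node._back(node.grad)
        return self

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- elementwise ------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))
        def back(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))
        out._back = back if _GRAD_ENABLED else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))
        def back(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._back = back if _GRAD_ENABLED else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))
        def back(g):
            self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))
        out._back = back if _GRAD_ENABLED else None
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        def back(g):
            self._accumulate(g * (1.0 - t * t))
        out._back = back if _GRAD_ENABLED else None
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        def back(g):
            self._accumulate(g * s * (1.0 - s))
        out._back = back if _GRAD_ENABLED else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        def back(g):
            self._accumulate(g * mask)
        out._back = back if _GRAD_ENABLED else None
        return out

    def gelu(self):
        x = self.data
        c = math.sqrt(2.0 / math.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), (self,))
        def back(g):
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x ** 2)
            self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))
        out._back = back if _GRAD_ENABLED else None
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def back(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).astype(np.float32))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).astype(np.float32))
        out._back = back if _GRAD_ENABLED else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        def back(g):
            self._accumulate(g.reshape(self.data.shape))
        out._back = back if _GRAD_ENABLED else None
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)
        def back(g):
            self._accumulate(g.transpose(*inv))
        out._back = back if _GRAD_ENABLED else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None))) for p in parts)
        def back(g):
            full = np.zeros_like(self.data)
            if basic:  # no duplicate positions in basic indexing
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)
        out._back = back if _GRAD_ENABLED else None
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    def back(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, gg in zip(tensors, splits):
            t._accumulate(gg)
    out._back = back if _GRAD_ENABLED else None
    return out


def softmax(x: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
    """Softmax over the last axis; ``mask`` positions (False) get -inf."""
    z = x.data
    if mask is not None:
        z = np.where(mask, z, np.float32(-1e9))
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s.astype(np.float32), (x,))
    def back(g):
        gs = g * s
        x._accumulate((gs - s * gs.sum(axis=-1, keepdims=True)).astype(np.float32))
    out._back = back if _GRAD_ENABLED else None
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray,
                         weights: Optional[np.ndarray] = None) -> Tensor:
    """Mean token-level cross-entropy from logits (N, V) and int targets (N,).

    ``weights`` (N,) scales each position's loss (0 = padding); the result is
    normalized by the total weight.
    """
    z = logits.data
    n = z.shape[0]
    w = np.ones(n, dtype=np.float32) if weights is None else weights.astype(np.float32)
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=-1))
    picked = z[np.arange(n), targets]
    total_w = max(float(w.sum()), 1e-8)
    loss = float(((lse - picked) * w).sum() / total_w)
    out = Tensor(np.float32(loss), (logits,))
    def back(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=-1, keepdims=True)
        p[np.arange(n), targets] -= 1.0
        logits._accumulate((g * p * (w / total_w)[:, None]).astype(np.float32))
    out._back = back if _GRAD_ENABLED else None
    return out


def bce_logits(logits: Tensor, targets: np.ndarray,
               sample_weights: Optional[np.ndarray] = None) -> Tensor:
    """Weighted binary cross-entropy from logits (N,) and {0,1} targets."""
    z = logits.data
    t = targets.astype(np.float32)
    w = np.ones_like(t) if sample_weights is None else sample_weights.astype(np.float32)
    # stable: max(z,0) - z*t + log(1 + exp(-|z|))
    per = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    total_w = max(float(w.sum()), 1e-8)
    out = Tensor(np.float32(float((per * w).sum() / total_w)), (logits,))
    def back(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate((g * (s - t) * w / total_w).astype(np.float32))
    out._back = back if _GRAD_ENABLED else None
    return out


# --------------------------------------------------------------------------
# Modules


class Parameter(Tensor):
    __slots__ = ()


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            p.data = a.astype(np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_glorot(rng, n_in, n_out, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(
            (rng.standard_normal((vocab, dim)) * (dim ** -0.5)).astype(np.float32))

    def __call__(self, ids: np.ndarray) -> Tensor:
        w = self.weight
        out = Tensor(w.data[ids], (w,))
        def back(g):
            full = np.zeros_like(w.data)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
            w._accumulate(full)
        out._back = back if _GRAD_ENABLED else None
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        g_, b_ = self.gamma, self.beta
        out = Tensor(xhat * g_.data + b_.data, (x, g_, b_))
        d = x.data.shape[-1]
        def back(g):
            b_._accumulate(_unbroadcast(g, b_.data.shape))
            g_._accumulate(_unbroadcast(g * xhat, g_.data.shape))
            gx = g * g_.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            x._accumulate(dx.astype(np.float32))
        out._back = back if _GRAD_ENABLED else None
        return out


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.data.shape) >= self.p).astype(np.float32)
        return x * (keep / (1.0 - self.p))


class LSTMCell(Module):
    """Fused LSTM step: one matmul for all four gates, one tape node each
    for the gate nonlinearity block."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.w = Parameter(_glorot(rng, n_in + n_hidden, 4 * n_hidden,
                                   (n_in + n_hidden, 4 * n_hidden)))
        b = np.zeros(4 * n_hidden, dtype=np.float32)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        nh = self.n_hidden
        z = concat([x, h], axis=-1) @ self.w + self.b
        zd = z.data
        i = 1.0 / (1.0 + np.exp(-zd[..., :nh]))
        f = 1.0 / (1.0 + np.exp(-zd[..., nh:2 * nh]))
        g_ = np.tanh(zd[..., 2 * nh:3 * nh])
        o = 1.0 / (1.0 + np.exp(-zd[..., 3 * nh:]))
        c_new = f * c.data + i * g_
        tc = np.tanh(c_new)
        h_new = o * tc
        out_h = Tensor(h_new, (z, c))
        out_c = Tensor(c_new, (z, c))
        def back_h(gh):
            dc_tot = gh * o * (1.0 - tc * tc)
            _lstm_gate_back(z, c, gh * tc, dc_tot, i, f, g_, o, nh)
        def back_c(gc):
            _lstm_gate_back(z, c, None, gc, i, f, g_, o, nh)
        out_h._back = back_h if _GRAD_ENABLED else None
        out_c._back = back_c if _GRAD_ENABLED else None
        return out_h, out_c


def _lstm_gate_back(z: Tensor, c: Tensor, do, dc_tot, i, f, g_, o, nh):
    dz = np.empty_like(z.data)
    dz[..., :nh] = dc_tot * g_ * i * (1.0 - i)
    dz[..., nh:2 * nh] = dc_tot * c.data * f * (1.0 - f)
    dz[..., 2 * nh:3 * nh] = dc_tot * i * (1.0 - g_ * g_)
    dz[..., 3 * nh:] = (do * o * (1.0 - o)) if do is not None else 0.0
    z._accumulate(dz)
    c._accumulate(dc_tot * f)


class GRUCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.w = Parameter(_glorot(rng, n_in, 3 * n_hidden, (n_in, 3 * n_hidden)))
        self.u = Parameter(_glorot(rng, n_hidden, 3 * n_hidden, (n_hidden, 3 * n_hidden)))
        self.b = Parameter(np.zeros(3 * n_hidden, dtype=np.float32))
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        nh = self.n_hidden
        xw = x @ self.w + self.b
        hu = h @ self.u
        a, b_, hd = xw.data, hu.data, h.data
        r = 1.0 / (1.0 + np.exp(-(a[..., :nh] + b_[..., :nh])))
        u_ = 1.0 / (1.0 + np.exp(-(a[..., nh:2 * nh] + b_[..., nh:2 * nh])))
        n_ = np.tanh(a[..., 2 * nh:] + r * b_[..., 2 * nh:])
        h_new = (1.0 - u_) * n_ + u_ * hd
        out = Tensor(h_new, (xw, hu, h))
        def back(g):
            dn = g * (1.0 - u_)
            du = g * (hd - n_) * u_ * (1.0 - u_)
            dpre_n = dn * (1.0 - n_ * n_)
            dr = dpre_n * b_[..., 2 * nh:] * r * (1.0 - r)
            dxw = np.concatenate([dr, du, dpre_n], axis=-1)
            dhu = np.concatenate([dr, du, dpre_n * r], axis=-1)
            xw._accumulate(dxw)
            hu._accumulate(dhu)
            h._accumulate(g * u_)
        out._back = back if _GRAD_ENABLED else None
        return out


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.o = Linear(dim, dim, rng)
        self.heads = heads
        self.dk = dim // heads

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.heads, self.dk).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 mask: Optional[np.ndarray] = None) -> Tensor:
        """mask: broadcastable boolean (B, 1|h, Tq, Tk); True = attend."""
        q = self._split(self.q(query))
        k = self._split(self.k(key))
        v = self._split(self.v(value))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dk))
        attn = softmax(scores, mask=mask)
        ctx = attn @ v
        b, h, t, dk = ctx.shape
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, t, h * dk)
        return self.o(ctx)


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None].astype(np.float32)
    i = np.arange(dim)[None, :].astype(np.float32)
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


# --------------------------------------------------------------------------
# Optimizers


class Optimizer:
    def __init__(self, params: Sequence[Parameter], lr: float):
        self.params = list(params)
        self.lr = lr
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is not None:
                self._update(i, p)

    def _update(self, i: int, p: Parameter) -> None:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class SGD(Optimizer):
    def __init__(self, params, lr=0.01, momentum=0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        self.v[i] = self.momentum * self.v[i] - self.lr * p.grad
        p.data += self.v[i]


class RMSprop(Optimizer):
    def __init__(self, params, lr=0.001, rho=0.9, eps=1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.s = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        self.s[i] = self.rho * self.s[i] + (1 - self.rho) * p.grad ** 2
        p.data -= self.lr * p.grad / (np.sqrt(self.s[i]) + self.eps)


class Adam(Optimizer):
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
        mhat = self.m[i] / (1 - self.b1 ** self.t)
        vhat = self.v[i] / (1 - self.b2 ** self.t)
        p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Optimizer):
    def __init__(self, params, lr=0.002, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
        self.u[i] = np.maximum(self.b2 * self.u[i], np.abs(p.grad))
        p.data -= (self.lr / (1 - self.b1 ** self.t)) * self.m[i] / (self.u[i] + self.eps)


class Nadam(Adam):
    def _update(self, i, p):
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
        mhat = self.m[i] / (1 - self.b1 ** (self.t + 1))
        vhat = self.v[i] / (1 - self.b2 ** self.t)
        m_bar = self.b1 * mhat + (1 - self.b1) * p.grad / (1 - self.b1 ** self.t)
        p.data -= self.lr * m_bar / (np.sqrt(vhat) + self.eps)


_OPTIMIZERS = {
    "sgd": SGD, "rmsprop": RMSprop, "adam": Adam,
    "adamax": Adamax, "nadam": Nadam,
}


def make_optimizer(name: str, params: Sequence[Parameter], lr: float) -> Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    return cls(params, lr=lr)
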