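"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the autoencoders need — affine maps, tanh,
concatenation, row gather/scatter and masked mean-square error — with a
topologically sorted backward pass, plus an Adam optimizer.  Float64
throughout; determinism is inherited from the caller's seeded RNG.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Linear", "Adam", "concat", "gather", "scatter_add", "masked_mse"]


class Tensor:
    __slots__ = ("data", "grad", "parents", "bw", "requires_grad")

    def __init__(self, data, parents=(), bw=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = parents
        self.bw = bw
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out.bw = bw
        return out

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out.bw = bw
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data - other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))

        out.bw = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out.bw = bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out.bw = bw
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad += g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.bw is not None and t.grad is not None:
                t.bw(t.grad)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors, axis=1):
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        chunks = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, c in zip(tensors, chunks):
            if t.requires_grad:
                t._accum(c)

    out.bw = bw
    return out


def gather(t: Tensor, idx) -> Tensor:
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], (t,))

    def bw(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accum(acc)

    out.bw = bw
    return out


def scatter_add(t: Tensor, idx, n_rows: int) -> Tensor:
    idx = np.asarray(idx)
    data = np.zeros((n_rows,) + t.data.shape[1:])
    np.add.at(data, idx, t.data)
    out = Tensor(data, (t,))

    def bw(g):
        if t.requires_grad:
            t._accum(g[idx])

    out.bw = bw
    return out


def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over entries where mask is 1 (padding excluded)."""
    diff = pred.data - target
    denom = float(mask.sum())
    out = Tensor(np.sum(mask * diff * diff) / denom, (pred,))

    def bw(g):
        if pred.requires_grad:
            pred._accum(g * 2.0 * mask * diff / denom)

    out.bw = bw
    return out


class Linear:
    """Affine layer with Xavier/Glorot initialisation."""

    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(6.0 / (n_in + n_out))
        self.w = Tensor(rng.uniform(-scale, scale, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    @property
    def params(self):
        return [self.w, self.b]


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
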