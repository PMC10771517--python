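"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model and losses in this package are small enough (subgraphs of a few
hundred nodes, embedding widths of 64-256) that a compact tape-based engine
in float64 is both fast enough and easy to verify against finite
differences. Only the operations the graph transformer needs are provided:
dense/sparse matmul, elementwise arithmetic with broadcasting, ReLU, clip,
exp/log/sqrt, reductions, concatenation, fancy indexing, and segment
(scatter) operations for per-node attention softmax.

Gradient convention: ``Tensor.backward()`` seeds the (scalar) output with 1
and accumulates ``.grad`` on every tensor created with
``requires_grad=True``.
"""

from __future__ import annotations

import contextlib

import numpy as np
import scipy.sparse as sp

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        # list of (parent Tensor, vjp function grad_out -> grad_parent)
        self._parents: list = []

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for p, vjp in t._parents:
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return take(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, shape):
        return reshape(self, shape)

    @property
    def T(self):
        return transpose(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        out._parents = [(p, f) for p, f in parents
                        if p.requires_grad or p._parents]
    return out


# -- primitive operations ----------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data,
                 [(a, lambda g: _unbroadcast(g, a.data.shape)),
                  (b, lambda g: _unbroadcast(g, b.data.shape))])


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data,
                 [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
                  (b, lambda g: _unbroadcast(g * a.data, b.data.shape))])


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data / b.data,
                 [(a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
                  (b, lambda g: _unbroadcast(-g * a.data / b.data ** 2,
                                             b.data.shape))])


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data @ b.data,
                 [(a, lambda g: g @ b.data.T),
                  (b, lambda g: a.data.T @ g)])


def spmm(s: sp.spmatrix, w: Tensor) -> Tensor:
    """Sparse (constant) @ dense (differentiable) matrix product."""
    s = sp.csr_matrix(s)
    w = as_tensor(w)
    return _make(np.asarray(s @ w.data), [(w, lambda g: np.asarray(s.T @ g))])


def transpose(a):
    a = as_tensor(a)
    return _make(a.data.T, [(a, lambda g: g.T)])


def reshape(a, shape):
    a = as_tensor(a)
    old = a.data.shape
    return _make(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return _make(np.where(mask, a.data, 0.0), [(a, lambda g: g * mask)])


def clip(a, lo=None, hi=None):
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = np.ones_like(a.data, dtype=bool)
    if lo is not None:
        inside &= a.data >= lo
    if hi is not None:
        inside &= a.data <= hi
    return _make(out, [(a, lambda g: g * inside)])


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)
    return _make(out, [(a, lambda g: g * out)])


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: g / a.data)])


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _make(out, [(a, lambda g: g * 0.5 / out)])


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.data.shape).copy()

    return _make(out, [(a, vjp)])


def mean(a, axis=None):
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis), 1.0 / n)


def take(a, key):
    a = as_tensor(a)

    def vjp(g):
        out = np.zeros_like(a.data)
        np.add.at(out, key, g)
        return out

    return _make(a.data[key], [(a, vjp)])


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return _make(out, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def segment_sum(a, seg: np.ndarray, n: int):
    """Sum rows (or entries) of `a` into `n` buckets given by `seg`."""
    a = as_tensor(a)
    shape = (n,) + a.data.shape[1:]
    out = np.zeros(shape)
    np.add.at(out, seg, a.data)
    return _make(out, [(a, lambda g: g[seg])])


def segment_softmax(scores, seg: np.ndarray, n: int):
    """Softmax of a 1-D score vector within segments (numerically stable).

    The per-segment max shift is treated as a constant, which is exact for
    softmax gradients.
    """
    scores = as_tensor(scores)
    m = np.full(n, -np.inf)
    np.maximum.at(m, seg, scores.data)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = add(scores, Tensor(-m[seg]))
    e = exp(shifted)
    denom = segment_sum(e, seg, n)
    return div(e, take(denom, seg))


def softmax_rows(a):
    a = as_tensor(a)
    shift = Tensor(-a.data.max(axis=1, keepdims=True))
    e = exp(add(a, shift))
    return div(e, tsum(e, axis=1, keepdims=True))


# -- parameters and optimizer ------------------------------------------------

class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Parameter(rng.uniform(-limit, limit, size=shape))


class Adam:
    """Adaptive-moment gradient descent with decoupled weight decay.

    Weight decay is applied multiplicatively to the parameter (not folded
    into the gradient); parameters listed in ``no_decay`` (biases, gates)
    are exempt.
    """

    def __init__(self, params: dict, lr=1e-3, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8, no_decay=()):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.no_decay = set(no_decay)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            if self.wd and k not in self.no_decay:
                p.data -= self.lr * self.wd * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
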