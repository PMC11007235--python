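"""Vectorized reverse-mode automatic differentiation on numpy arrays.

This is the numerical core of the package: every energy term, geometric
primitive and forward-kinematics step is expressed through the operations
defined here, so the total conformational energy is a single differentiable
graph from atom coordinates (or torsion angles) down to a scalar, and
``backward()`` yields exact analytic gradients for relaxation.

Only the operations the force field needs are implemented.  All math
functions in this module dispatch on their argument type: given plain
numpy input they call numpy directly (no tape is built), given a
:class:`Tensor` they record the operation for the backward pass.  Code
written against these functions therefore runs fast when gradients are
not needed and differentiably when they are.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "value_of",
    "is_tensor",
    "exp",
    "log",
    "sqrt",
    "sin",
    "cos",
    "tanh",
    "sigmoid",
    "arctan2",
    "tsum",
    "tmean",
    "where",
    "clamp_min",
    "gather",
    "scatter_add",
    "stack",
    "concatenate",
    "expand_dims",
    "dot",
    "cross",
    "norm",
    "normalize",
    "logsumexp",
    "softmin_weights",
]


class Tensor:
    """A numpy array with a gradient tape.

    Parameters
    ----------
    value
        Array data (converted to float64).
    parents
        Sequence of ``(tensor, vjp)`` pairs where ``vjp`` maps the output
        gradient to the contribution to that parent's gradient.
    """

    __slots__ = ("value", "grad", "_parents")

    # make numpy defer to the reflected dunder ops instead of iterating
    __array_ufunc__ = None

    def __init__(self, value, parents: Sequence = ()):  # noqa: ANN001
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @property
    def size(self):
        return self.value.size

    def __len__(self):
        return len(self.value)

    def __repr__(self):
        return f"Tensor({self.value!r})"

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> np.ndarray:
        return self.value.copy()

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar) tensor into the graph."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.value)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS topological sort (graphs can be deep: forward kinematics)
        visiting: list[tuple[Tensor, int]] = [(self, 0)]
        seen.add(id(self))
        while visiting:
            node, i = visiting.pop()
            parents = node._parents
            while i < len(parents):
                child = parents[i][0]
                if id(child) not in seen:
                    seen.add(id(child))
                    visiting.append((node, i + 1))
                    visiting.append((child, 0))
                    break
                i += 1
            else:
                order.append(node)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in node._parents:
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, [(self, lambda g: -g)])

    def __sub__(self, other):
        if is_tensor(other):
            return add(self, -other)
        return add(self, -np.asarray(other, dtype=np.float64))

    def __rsub__(self, other):
        return add(-self, other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("Tensor ** only supports scalar exponents")
        v = self.value ** p
        return Tensor(v, [(self, lambda g: _unbroadcast(g * p * self.value ** (p - 1), self.shape))])

    def __getitem__(self, idx):
        return gather(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.value.reshape(shape), [(self, lambda g: g.reshape(old))])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None):
        return tmean(self, axis=axis)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def value_of(x) -> np.ndarray:
    """Underlying numpy value of a Tensor, or the input as an array."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    grad = np.asarray(grad, dtype=np.float64)
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# binary ops
# ---------------------------------------------------------------------------

def add(a, b):
    if not (is_tensor(a) or is_tensor(b)):
        return np.add(a, b)
    parents = []
    av, bv = value_of(a), value_of(b)
    if is_tensor(a):
        parents.append((a, lambda g: _unbroadcast(g, a.shape)))
    if is_tensor(b):
        parents.append((b, lambda g: _unbroadcast(g, b.shape)))
    return Tensor(av + bv, parents)


def mul(a, b):
    if not (is_tensor(a) or is_tensor(b)):
        return np.multiply(a, b)
    av, bv = value_of(a), value_of(b)
    parents = []
    if is_tensor(a):
        parents.append((a, lambda g: _unbroadcast(g * bv, a.shape)))
    if is_tensor(b):
        parents.append((b, lambda g: _unbroadcast(g * av, b.shape)))
    return Tensor(av * bv, parents)


def div(a, b):
    if not (is_tensor(a) or is_tensor(b)):
        return np.divide(a, b)
    av, bv = value_of(a), value_of(b)
    parents = []
    if is_tensor(a):
        parents.append((a, lambda g: _unbroadcast(g / bv, a.shape)))
    if is_tensor(b):
        parents.append((b, lambda g: _unbroadcast(-g * av / (bv * bv), b.shape)))
    return Tensor(av / bv, parents)


def arctan2(y, x):
    if not (is_tensor(y) or is_tensor(x)):
        return np.arctan2(y, x)
    yv, xv = value_of(y), value_of(x)
    denom = xv * xv + yv * yv
    parents = []
    if is_tensor(y):
        parents.append((y, lambda g: _unbroadcast(g * xv / denom, y.shape)))
    if is_tensor(x):
        parents.append((x, lambda g: _unbroadcast(-g * yv / denom, x.shape)))
    return Tensor(np.arctan2(yv, xv), parents)


# ---------------------------------------------------------------------------
# elementwise unary ops
# ---------------------------------------------------------------------------

def _unary(x, fwd: Callable, dfn: Callable):
    if not is_tensor(x):
        return fwd(np.asarray(x, dtype=np.float64))
    v = fwd(x.value)
    return Tensor(v, [(x, lambda g: g * dfn(x.value, v))])


def exp(x):
    return _unary(x, np.exp, lambda xv, v: v)


def log(x):
    return _unary(x, np.log, lambda xv, v: 1.0 / xv)


def sqrt(x):
    return _unary(x, np.sqrt, lambda xv, v: 0.5 / v)


def sin(x):
    return _unary(x, np.sin, lambda xv, v: np.cos(xv))


def cos(x):
    return _unary(x, np.cos, lambda xv, v: -np.sin(xv))


def tanh(x):
    return _unary(x, np.tanh, lambda xv, v: 1.0 - v * v)


def _sigmoid_np(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x):
    return _unary(
        x,
        lambda v: _sigmoid_np(np.atleast_1d(v)).reshape(np.shape(v)),
        lambda xv, v: v * (1.0 - v),
    )


# ---------------------------------------------------------------------------
# reductions / structure
# ---------------------------------------------------------------------------

def tsum(x, axis=None, keepdims=False):
    if not is_tensor(x):
        return np.sum(x, axis=axis, keepdims=keepdims)
    v = x.value.sum(axis=axis, keepdims=keepdims)
    shape = x.shape

    def vjp(g):
        g = np.asarray(g, dtype=np.float64)
        if axis is None:
            return np.broadcast_to(g, shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, shape).copy()

    return Tensor(v, [(x, vjp)])


def tmean(x, axis=None):
    if not is_tensor(x):
        return np.mean(x, axis=axis)
    n = x.size if axis is None else x.shape[axis]
    return tsum(x, axis=axis) / float(n)


def where(cond, a, b):
    """Branch on a *non-differentiable* boolean condition."""
    cond = np.asarray(value_of(cond), dtype=bool)
    if not (is_tensor(a) or is_tensor(b)):
        return np.where(cond, a, b)
    av, bv = value_of(a), value_of(b)
    parents = []
    if is_tensor(a):
        parents.append((a, lambda g: _unbroadcast(np.where(cond, g, 0.0), a.shape)))
    if is_tensor(b):
        parents.append((b, lambda g: _unbroadcast(np.where(cond, 0.0, g), b.shape)))
    return Tensor(np.where(cond, av, bv), parents)


def clamp_min(x, lo: float):
    """max(x, lo); gradient is zero on the clamped branch."""
    return where(value_of(x) < lo, lo * np.ones_like(value_of(x)), x)


def gather(x, idx):
    if not is_tensor(x):
        return np.asarray(x)[idx]
    v = x.value[idx]
    shape = x.shape

    def vjp(g):
        out = np.zeros(shape, dtype=np.float64)
        np.add.at(out, idx, g)
        return out

    return Tensor(v, [(x, vjp)])


def scatter_add(values, index, size: int):
    """out[k] = sum of values[i] where index[i] == k; out has length ``size``."""
    index = np.asarray(index, dtype=np.intp)
    if not is_tensor(values):
        out = np.zeros(size, dtype=np.float64)
        np.add.at(out, index, values)
        return out
    out = np.zeros(size, dtype=np.float64)
    np.add.at(out, index, values.value)
    return Tensor(out, [(values, lambda g: g[index])])


def stack(xs, axis=0):
    if not any(is_tensor(x) for x in xs):
        return np.stack(xs, axis=axis)
    vals = [value_of(x) for x in xs]
    out = np.stack(vals, axis=axis)
    parents = []
    for i, x in enumerate(xs):
        if is_tensor(x):
            parents.append((x, lambda g, i=i: np.take(g, i, axis=axis)))
    return Tensor(out, parents)


def concatenate(xs, axis=0):
    if not any(is_tensor(x) for x in xs):
        return np.concatenate(xs, axis=axis)
    vals = [value_of(x) for x in xs]
    out = np.concatenate(vals, axis=axis)
    offsets = np.cumsum([0] + [v.shape[axis] for v in vals])
    parents = []
    for i, x in enumerate(xs):
        if is_tensor(x):
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            parents.append((x, lambda g, sl=tuple(sl): g[sl]))
    return Tensor(out, parents)


# ---------------------------------------------------------------------------
# vector helpers (last-axis 3-vectors)
# ---------------------------------------------------------------------------

def dot(a, b, axis=-1):
    return tsum(mul(a, b), axis=axis)


def cross(a, b):
    if not (is_tensor(a) or is_tensor(b)):
        return np.cross(a, b)
    av, bv = value_of(a), value_of(b)
    parents = []
    if is_tensor(a):
        parents.append((a, lambda g: _unbroadcast(np.cross(bv, g), a.shape)))
    if is_tensor(b):
        parents.append((b, lambda g: _unbroadcast(np.cross(g, av), b.shape)))
    return Tensor(np.cross(av, bv), parents)


def norm(x, axis=-1, eps: float = 0.0):
    """Euclidean norm along ``axis``; ``eps`` guards the sqrt near zero."""
    s = tsum(mul(x, x), axis=axis)
    if eps:
        s = s + eps
    return sqrt(s)


def expand_dims(x, axis):
    if not is_tensor(x):
        return np.expand_dims(x, axis)
    old = x.shape
    return Tensor(np.expand_dims(x.value, axis), [(x, lambda g: g.reshape(old))])


def normalize(x, axis=-1, eps: float = 1e-12):
    n = norm(x, axis=axis, eps=eps)
    if np.ndim(value_of(x)) == 1:
        return div(x, n)
    return div(x, expand_dims(n, axis))


def logsumexp(x, axis=None):
    """log(sum(exp(x))); max-shifted for stability, grad-correct."""
    m = np.max(value_of(x), axis=axis, keepdims=True)
    shifted = add(x, -m) if is_tensor(x) else x - m
    s = tsum(exp(shifted), axis=axis)
    out = add(log(s), np.squeeze(m, axis=axis) if axis is not None else float(np.squeeze(m)))
    return out


def softmin_weights(x, tau: float):
    """Differentiable soft-min weights: softmax(-x / tau) along the last axis."""
    z = mul(x, -1.0 / tau)
    m = np.max(value_of(z), axis=-1, keepdims=True)
    e = exp(add(z, -m))
    return div(e, tsum(e, axis=-1, keepdims=True))
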