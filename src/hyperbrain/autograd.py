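"""Minimal reverse-mode automatic differentiation over numpy arrays.

The hyperbolic graph layers need gradients of compositions of Mobius
operations, exp/log maps and an unrolled Frechet-mean fixed-point
iteration.  This module provides just the primitives those layers use:
a :class:`Tensor` wrapping a float64 ndarray, broadcasting-aware binary
ops, a few elementwise transcendentals, reductions, indexing, and a
topological-order backward pass.

Every generic function here (``tanh``, ``norm``, ``where``, ...) accepts
either a :class:`Tensor` or a plain ndarray/scalar and returns the same
kind, so downstream geometry code is written once and runs with or
without gradient tracking (inference uses raw arrays).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor", "astensor", "data", "is_tensor",
    "tanh", "artanh", "exp", "log", "sqrt", "sigmoid", "softplus",
    "norm", "clamp", "where", "tsum", "matmul", "reshape", "take",
    "Adam",
]


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = len(shape)
    while g.ndim > nd:
        g = g.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    """Array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # let ndarray <op> Tensor defer to the reflected Tensor operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = ()  # tuple of (Tensor, grad_fn)

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data, parents):
        parents = tuple((p, f) for p, f in parents if p.requires_grad)
        out = Tensor(data, requires_grad=bool(parents))
        out._parents = parents
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative DFS post-order: inputs before consumers
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._parents:
                for p, fn in node._parents:
                    pg = _unbroadcast(fn(g), p.data.shape)
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        o = astensor(other)
        return Tensor._make(self.data + o.data,
                            [(self, lambda g: g), (o, lambda g: g)])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        o = astensor(other)
        return Tensor._make(self.data - o.data,
                            [(self, lambda g: g), (o, lambda g: -g)])

    def __rsub__(self, other):
        o = astensor(other)
        return Tensor._make(o.data - self.data,
                            [(self, lambda g: -g), (o, lambda g: g)])

    def __mul__(self, other):
        o = astensor(other)
        return Tensor._make(self.data * o.data,
                            [(self, lambda g: g * o.data),
                             (o, lambda g: g * self.data)])

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = astensor(other)
        return Tensor._make(self.data / o.data,
                            [(self, lambda g: g / o.data),
                             (o, lambda g: -g * self.data / (o.data ** 2))])

    def __rtruediv__(self, other):
        o = astensor(other)
        return o.__truediv__(self)

    def __pow__(self, n):
        if not np.isscalar(n):
            raise TypeError("only scalar exponents are supported")
        return Tensor._make(self.data ** n,
                            [(self, lambda g: g * n * self.data ** (n - 1))])

    def __matmul__(self, other):
        o = astensor(other)
        a, b = self.data, o.data
        return Tensor._make(
            a @ b,
            [(self, lambda g: np.matmul(g, np.swapaxes(b, -1, -2))),
             (o, lambda g: np.matmul(np.swapaxes(a, -1, -2), g))])

    def __rmatmul__(self, other):
        return astensor(other).__matmul__(self)

    def __getitem__(self, idx):
        def back(g, idx=idx):
            z = np.zeros_like(self.data)
            np.add.at(z, idx, g)
            return z
        return Tensor._make(self.data[idx], [(self, back)])

    # -- methods used by the generic functions --------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor._make(self.data.reshape(*shape),
                            [(self, lambda g: g.reshape(orig))])

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape)
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape)
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            [(self, back)])

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor._make(y, [(self, lambda g: g * (1.0 - y * y))])

    def artanh(self):
        x = self.data
        return Tensor._make(np.arctanh(x), [(self, lambda g: g / (1.0 - x * x))])

    def exp(self):
        y = np.exp(self.data)
        return Tensor._make(y, [(self, lambda g: g * y)])

    def log(self):
        x = self.data
        return Tensor._make(np.log(x), [(self, lambda g: g / x)])

    def sqrt(self):
        y = np.sqrt(self.data)
        return Tensor._make(y, [(self, lambda g: g * 0.5 / y)])

    def sigmoid(self):
        y = expit(self.data)
        return Tensor._make(y, [(self, lambda g: g * y * (1.0 - y))])

    def softplus(self):
        x = self.data
        return Tensor._make(np.logaddexp(0.0, x),
                            [(self, lambda g: g * expit(x))])

    def norm(self, axis=-1, keepdims=True):
        n = np.linalg.norm(self.data, axis=axis, keepdims=keepdims)
        x = self.data

        def back(g):
            nn = n if keepdims else np.expand_dims(n, axis)
            gg = g if keepdims else np.expand_dims(g, axis)
            return gg * x / np.maximum(nn, 1e-15)
        return Tensor._make(n, [(self, back)])

    def clamp(self, min=None, max=None):
        y = np.clip(self.data, min, max)
        mask = np.ones_like(self.data)
        if min is not None:
            mask = mask * (self.data > min)
        if max is not None:
            mask = mask * (self.data < max)
        return Tensor._make(y, [(self, lambda g: g * mask)])

    def t(self):
        """2-D transpose."""
        return Tensor._make(self.data.T, [(self, lambda g: g.T)])

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# generic (Tensor-or-ndarray) functional interface
# ---------------------------------------------------------------------------

def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def data(x) -> np.ndarray:
    """Underlying ndarray of a Tensor, or the input itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def tanh(x):
    return x.tanh() if is_tensor(x) else np.tanh(x)


def artanh(x):
    return x.artanh() if is_tensor(x) else np.arctanh(x)


def exp(x):
    return x.exp() if is_tensor(x) else np.exp(x)


def log(x):
    return x.log() if is_tensor(x) else np.log(x)


def sqrt(x):
    return x.sqrt() if is_tensor(x) else np.sqrt(x)


def sigmoid(x):
    return x.sigmoid() if is_tensor(x) else expit(x)


def softplus(x):
    return x.softplus() if is_tensor(x) else np.logaddexp(0.0, x)


def norm(x, axis=-1, keepdims=True):
    if is_tensor(x):
        return x.norm(axis=axis, keepdims=keepdims)
    return np.linalg.norm(x, axis=axis, keepdims=keepdims)


def clamp(x, min=None, max=None):
    if is_tensor(x):
        return x.clamp(min=min, max=max)
    return np.clip(x, min, max)


def where(cond, a, b):
    """Select with a *constant* (ndarray) condition."""
    cond = np.asarray(cond, dtype=bool)
    if is_tensor(a) or is_tensor(b):
        ta, tb = astensor(a), astensor(b)
        return Tensor._make(np.where(cond, ta.data, tb.data),
                            [(ta, lambda g: g * cond),
                             (tb, lambda g: g * ~cond)])
    return np.where(cond, a, b)


def tsum(x, axis=None, keepdims=False):
    if is_tensor(x):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def matmul(a, b):
    if is_tensor(a) or is_tensor(b):
        return astensor(a) @ astensor(b)
    return a @ b


def reshape(x, *shape):
    if len(shape) == 1 and isinstance(shape[0], tuple):
        shape = shape[0]
    if is_tensor(x):
        return x.reshape(*shape) if shape else x.reshape(())
    return np.reshape(x, shape)


def take(x, idx):
    """Gather rows/elements; differentiable scatter-add on backward."""
    if is_tensor(x):
        return x[idx]
    return x[idx]


def transpose(x):
    """2-D transpose."""
    return x.t() if is_tensor(x) else np.asarray(x).T


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam over leaf Tensors (all model parameters here are Euclidean:
    weights, origin-tangent biases and unconstrained curvature raws)."""

    def __init__(self, params, lr=0.02, betas=(0.9, 0.999), eps=1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
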