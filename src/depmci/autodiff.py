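"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the temporal model: broadcast-aware elementwise
arithmetic, batched matmul, softmax, sigmoid/GELU, reductions, reshaping,
zero-padding and (fancy) indexing.  A :class:`Tensor` records its parents and
a local backward rule; :meth:`Tensor.backward` runs the tape in reverse
topological order.

Deliberately small rather than general: no in-place ops, no higher-order
gradients, float64 throughout (the model is desk-scale, and exactness in the
oracle tests matters more than speed).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "sigmoid", "gelu", "softmax", "concat"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if self.requires_grad and self.grad is not None:
            self.grad += _unbroadcast(np.asarray(grad), self.data.shape)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data),
                                   other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / other.data**2),
        )
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions / shape ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            if self.requires_grad and self.grad is not None:
                np.add.at(self.grad, key, g)

        out._backward = bw
        return out

    def pad(self, axis: int, before: int, after: int):
        """Zero-pad along one axis."""
        widths = [(0, 0)] * self.data.ndim
        widths[axis] = (before, after)
        out = Tensor(np.pad(self.data, widths), _parents=(self,))
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + self.data.shape[axis])
        sl = tuple(sl)
        out._backward = lambda g: self._accum(g[sl])
        return out


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear-unit: x * Phi(x)."""
    x = Tensor.as_tensor(x)
    phi_cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data**2)
    out = Tensor(x.data * phi_cdf, _parents=(x,))
    out._backward = lambda g: x._accum(g * (phi_cdf + x.data * pdf))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor.as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    out._backward = bw
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            t._accum(g[tuple(sl)])
            start += s

    out._backward = bw
    return out
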