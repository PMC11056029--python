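"""Minimal reverse-mode automatic differentiation over numpy arrays.

The pathway network is small (two sparse/dense layers, one attention block,
a short MLP), so a compact tape-based autograd is sufficient and keeps the
whole stack dependency-free beyond numpy.  Gradients flow both into
parameters (for training) and into input matrices (for attribution), which
is why a generic engine is used instead of hand-coded layer backprops.

All arrays are float64.  Broadcasting in ``+`` and ``*`` is supported; the
backward pass sums gradients over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = None
        self.name = name

    # ---- shape helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ----------------------------------------------------
    def _lift(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = _backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = _backward
        return out

    __matmul__ = matmul

    # ---- nonlinearities ------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        out._backward = _backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = _backward
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _backward
        return out

    # ---- reductions / reshaping ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_column(self, j: int) -> "Tensor":
        out = Tensor(self.data[:, j], self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, j] = g
                self._accum(full)

        out._backward = _backward
        return out

    def take_row(self, i: int) -> "Tensor":
        out = Tensor(self.data[i], self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[i] = g
                self._accum(full)

        out._backward = _backward
        return out

    # ---- plumbing ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        """Reverse-accumulate gradients from this tensor.

        `grad` defaults to ones (i.e. d(sum of self)/d(leaf)).
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
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

        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Differentiable concatenation along `axis`."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = _backward
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax with the standard max-shift for stability."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def _backward(g):
        if x.requires_grad:
            # dL/dx = y * (g - sum_j g_j y_j)
            dot = (g * y).sum(axis=-1, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = _backward
    return out
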