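"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for each operation, a
closure that maps the output gradient to gradients of the inputs.  Calling
:meth:`Tensor.backward` on a scalar walks the graph in reverse topological
order and accumulates ``.grad`` on every tensor created with
``requires_grad=True``.  Only the operations needed by the models in this
package are provided; all arrays follow the NCHW layout for images.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd ------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and (p.requires_grad or p._parents):
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not (parent.requires_grad or parent._parents):
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            a_shape, b_shape = self.data.shape, other.data.shape
            out._backward = lambda g: (_unbroadcast(g, a_shape), _unbroadcast(g, b_shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        c = float(exponent)
        out = _make(self.data ** c, (self,))
        if out._parents:
            x = self.data
            out._backward = lambda g: (g * c * x ** (c - 1.0),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out._parents:
            a, b = self, other

            def bw(g):
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

            out._backward = bw
        return out

    # -- reductions and shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            shape = self.data.shape

            def bw(g):
                if axis is None:
                    return (np.broadcast_to(g, shape).copy(),)
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                return (np.broadcast_to(g, shape).copy(),)

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            orig = self.data.shape
            out._backward = lambda g: (g.reshape(orig),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _make(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        if out._parents:
            inv = np.argsort(axes)
            out._backward = lambda g: (g.transpose(inv),)
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            x = self.data
            out._backward = lambda g: (g / x,)
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out._parents:
            s = np.sign(self.data)
            out._backward = lambda g: (g * s,)
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        if out._parents:
            out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(y, (self,))
        if out._parents:
            out._backward = lambda g: (g * y * (1.0 - y),)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = _make(data, tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward = bw
    return out


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Look up rows of a (K, d) table by an integer index array.

    The backward pass scatter-adds gradients onto the selected rows, which
    is what codebook updates through the alignment loss require.
    """
    idx = np.asarray(indices)
    out = _make(table.data[idx], (table,))
    if out._parents:
        shape = table.data.shape

        def bw(g):
            gt = np.zeros(shape, dtype=g.dtype)
            np.add.at(gt, idx.reshape(-1), g.reshape(-1, shape[-1]))
            return (gt,)

        out._backward = bw
    return out
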