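"""Compact reverse-mode automatic differentiation over NumPy arrays.

The model components in this package (1D convolutions, recurrent encoders,
message-passing graph layers, attention, fully connected heads) are expressed
as small computation graphs of :class:`Tensor` operations.  Gradients are
obtained by reverse-mode accumulation over a dynamically recorded tape.

Only the operations the models actually use are implemented.  Sparse
constants (graph aggregation operators) enter through :func:`spmm`, whose
left operand is a fixed ``scipy.sparse`` matrix and therefore never receives
a gradient.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "concat", "spmm", "gather_rows", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate gradients in ``.grad``
    after :meth:`backward`.  Everything is float64: at the problem sizes this
    package targets, exact reproducibility is worth more than speed.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._node(self.data / other.data, (self, other), bwd)

    def __pow__(self, exponent: float):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._node(self.data**exponent, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._node(self.data @ other.data, (self, other), bwd)

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._node(self.data.reshape(*shape), (self,), bwd)

    @property
    def T(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g.T)

        return Tensor._node(self.data.T, (self,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def leaky_relu(self, negative_slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, negative_slope)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._node(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._node(out_data, (self,), bwd)

    def softmax_rows(self):
        """Row-wise softmax of a 2D tensor (numerically shifted)."""
        shifted = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=1, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=1, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._node(out_data, (self,), bwd)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Multiply a constant sparse matrix by a dense tensor: ``matrix @ x``.

    Used for neighbor aggregation and graph readout; the sparse operator is
    data-derived and carries no gradient.
    """
    x = as_tensor(x)
    matrix = matrix.tocsr()

    def bwd(g):
        if x.requires_grad:
            x._accum(matrix.T @ g)

    return Tensor._node(matrix @ x.data, (x,), bwd)


def gather_rows(x: Tensor, index) -> Tensor:
    """Select rows ``x[index]``; backward scatter-adds into the source."""
    x = as_tensor(x)
    index = np.asarray(index, dtype=np.intp)

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, index, g)
            x._accum(acc)

    return Tensor._node(x.data[index], (x,), bwd)
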