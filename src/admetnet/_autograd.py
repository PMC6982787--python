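"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core used by the fingerprint dense networks and the
graph convolutional networks.  It supports exactly the operations those
architectures need (affine maps, ReLU/tanh, sparse neighbour aggregation,
segment mean/max readout, elementwise arithmetic with broadcasting) and
nothing else.  Gradients are accumulated by a topological backward sweep;
correctness is property-tested against central finite differences.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "concat", "sparse_matmul", "segment_max", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _track(*parents) -> bool:
        return any(p.requires_grad or p._parents for p in parents)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other) if self._track(self, other) else ())

        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,) if self._track(self) else ())

        def backward(g):
            self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other) if self._track(self, other) else ())

        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,) if self._track(self) else ())

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    # -- linear algebra --------------------------------------------------
    def matmul(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other) if self._track(self, other) else ())

        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _parents=(self,) if self._track(self) else ())

        def backward(g):
            self._accumulate(g * mask)

        out._backward = backward
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor(value, _parents=(self,) if self._track(self) else ())

        def backward(g):
            self._accumulate(g * (1.0 - value * value))

        out._backward = backward
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,) if self._track(self) else ())

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    # -- autodiff driver --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, differentiable in every input."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 _parents=tuple(t for t in tensors if t.requires_grad or t._parents))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    out._backward = backward
    return out


def sparse_matmul(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Product A @ x with a constant sparse matrix A (e.g. block adjacency)."""
    matrix = matrix.tocsr()
    out = Tensor(matrix @ x.data, _parents=(x,) if x.requires_grad or x._parents else ())

    def backward(g):
        x._accumulate(matrix.T @ g)

    out._backward = backward
    return out


def gather_rows(x: Tensor, indices: np.ndarray) -> Tensor:
    """Row selection x[indices]; backward scatter-adds into the source rows."""
    indices = np.asarray(indices)
    out = Tensor(x.data[indices], _parents=(x,) if x.requires_grad or x._parents else ())

    def backward(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, indices, g)
        x._accumulate(acc)

    out._backward = backward
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Per-column maximum over contiguous row segments (graph readout).

    `segment_ids` must be sorted ascending and cover 0..n_segments-1.
    Gradient at ties is split evenly among the tied rows, a valid
    subgradient that also keeps the total gradient mass per segment exact.
    """
    segment_ids = np.asarray(segment_ids)
    starts = np.searchsorted(segment_ids, np.arange(n_segments))
    value = np.maximum.reduceat(x.data, starts, axis=0)
    out = Tensor(value, _parents=(x,) if x.requires_grad or x._parents else ())

    def backward(g):
        is_max = x.data == value[segment_ids]
        counts = np.zeros((n_segments, x.data.shape[1]))
        np.add.at(counts, segment_ids, is_max)
        x._accumulate(is_max * (g / counts)[segment_ids])

    out._backward = backward
    return out
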