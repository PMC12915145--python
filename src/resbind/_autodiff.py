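"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the neural-network modules: a
:class:`Tensor` wraps a float64 ndarray and records enough of the
computation graph to back-propagate gradients.  Only the operations the
binding-site model needs are implemented (broadcast arithmetic, batched
matmul, slicing/gather, padding, reductions, and the usual pointwise
nonlinearities).  Everything is single-threaded and deterministic.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "pad_axis"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray/Tensor arithmetic to our operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction -------------------------------------------
    @staticmethod
    def _make(data, parents: Iterable["Tensor"], backward):
        parents = tuple(parents)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            # may alias the incoming array; gradients are never mutated in place
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be a few hundred nodes deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        if self.grad is None:  # root does not require grad: nothing to do
            return
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    # python scalars take a dedicated path so they do not promote
    # single-precision arrays to double precision
    def __add__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            c = float(other)

            def bw(g, a=self):
                a._accumulate(g)

            return Tensor._make(self.data + c, (self,), bw)
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return self + (-float(other))
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return (-self) + float(other)
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            c = float(other)

            def bw(g, a=self, c=c):
                a._accumulate(g * c)

            return Tensor._make(self.data * c, (self,), bw)
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return self * (1.0 / float(other))
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accumulate(_unbroadcast(g / b.data, a.shape))
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            c = float(other)
            out_data = c / self.data

            def bw(g, a=self, o=out_data):
                a._accumulate(-g * o / a.data)

            return Tensor._make(out_data, (self,), bw)
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g, a=self, c=float(exponent)):
            a._accumulate(g * c * np.power(a.data, c - 1.0))

        return Tensor._make(np.power(self.data, exponent), (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accumulate(_unbroadcast(ga, a.shape))
            b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    # -- shaping -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            a._accumulate(g.reshape(a.shape))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        def bw(g, a=self, i=ax1, j=ax2):
            a._accumulate(g.swapaxes(i, j))

        return Tensor._make(self.data.swapaxes(ax1, ax2), (self,), bw)

    def __getitem__(self, idx):
        def bw(g, a=self, idx=idx):
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accumulate(buf)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- pointwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a._accumulate(g * o)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g, a=self):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, o=out_data):
            a._accumulate(g * 0.5 / o)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self, o=out_data):
            a._accumulate(g * o * (1.0 - o))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        def bw(g, a=self):
            a._accumulate(g * (a.data > 0))

        return Tensor._make(np.maximum(self.data, 0.0), (self,), bw)

    def clip(self, lo: float, hi: float):
        def bw(g, a=self, lo=lo, hi=hi):
            a._accumulate(g * ((a.data >= lo) & (a.data <= hi)))

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def pad_axis(x: Tensor, axis: int, before: int, after: int) -> Tensor:
    """Zero-pad ``x`` along ``axis``; the inverse slice carries the gradient."""
    pad = [(0, 0)] * x.ndim
    pad[axis] = (before, after)

    def bw(g, a=x, axis=axis, before=before, after=after):
        sl = [slice(None)] * a.ndim
        sl[axis] = slice(before, before + a.shape[axis])
        a._accumulate(g[tuple(sl)])

    return Tensor._make(np.pad(x.data, pad), (x,), bw)
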