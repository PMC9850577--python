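"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Purpose-built tape-based autodiff: just the operations the recurrent
encoder/decoder and its losses need (dense matmul, elementwise nonlinearities,
row gather for embeddings, log-softmax NLL). Everything runs in float64 on a
single thread, so repeated runs with the same seed are bit-identical.

Gradient correctness is guarded by central-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "zeros", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def square(self):
        return self * self

    # -- nonlinearities ----------------------------------------------------
    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def softplus(self):
        # log(1 + e^x), computed stably; gradient is sigmoid(x)
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g / (1.0 + np.exp(-self.data)))
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), _prev=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def take_rows(self, idx):
        """Row gather (embedding lookup): out[i] = self[idx[i]]."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = bw
        return out

    def log_softmax(self):
        x = self.data
        m = x.max(axis=-1, keepdims=True)
        lse = m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True))
        y = x - lse
        out = Tensor(y, _prev=(self,))

        def bw(g):
            p = np.exp(y)
            self._accum(g - p * g.sum(axis=-1, keepdims=True))

        out._backward = bw
        return out

    def gather_last(self, idx):
        """out[i] = self[i, idx[i]] for a 2-D tensor (per-row pick)."""
        idx = np.asarray(idx, dtype=np.intp)
        rows = np.arange(self.data.shape[0])
        out = Tensor(self.data[rows, idx], _prev=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            acc[rows, idx] = g
            self._accum(acc)

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor (axis 0)."""
    out = Tensor(np.stack([t.data for t in tensors]), _prev=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(g[i])

    out._backward = bw
    return out
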