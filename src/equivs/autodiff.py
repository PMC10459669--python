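"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The bioactivity network is trained on CPU; this tape-based engine provides
exactly the operations its message-passing, readout, attention and loss
computations need (dense matmul, broadcasting arithmetic, segment sums for
graph aggregation, row gathers for edge endpoints, softmax, elementwise
nonlinearities).  Gradients are accumulated by topological traversal of the
recorded graph.  Every operation's backward pass is validated against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        value,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], tuple] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value)
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        """Accumulate gradients of self (must be scalar) into the graph."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order DFS
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node.parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.value + other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.value.shape),
                _unbroadcast(g, other.value.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.value * other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.value, self.value.shape),
                _unbroadcast(g * self.value, other.value.shape),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.value / other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.value, self.value.shape),
                _unbroadcast(-g * self.value / other.value**2, other.value.shape),
            ),
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.value @ other.value,
            (self, other),
            lambda g: (g @ other.value.T, self.value.T @ g),
        )
        return out

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        val = self.value.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.value.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.value.shape).copy(),)

        return Tensor(val, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.value.shape
        return Tensor(
            self.value.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def gather(self, idx: np.ndarray):
        """Select rows by integer index (with repetition)."""
        idx = np.asarray(idx)

        def bw(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.value[idx], (self,), bw)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.value > 0
        return Tensor(self.value * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = expit(self.value)
        return Tensor(s, (self,), lambda g: (g * s * (1.0 - s),))

    def tanh(self):
        t = np.tanh(self.value)
        return Tensor(t, (self,), lambda g: (g * (1.0 - t * t),))

    def exp(self):
        e = np.exp(self.value)
        return Tensor(e, (self,), lambda g: (g * e,))

    def square(self):
        return self * self

    def softmax(self, axis: int = -1):
        z = self.value - self.value.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            inner = (g * p).sum(axis=axis, keepdims=True)
            return (p * (g - inner),)

        return Tensor(p, (self,), bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = list(tensors)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis), tensors, bw)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row segment ids."""
    segment_ids = np.asarray(segment_ids)
    out = np.zeros((num_segments,) + t.value.shape[1:], dtype=t.value.dtype)
    np.add.at(out, segment_ids, t.value)
    return Tensor(out, (t,), lambda g: (g[segment_ids],))
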