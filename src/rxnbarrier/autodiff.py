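"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the message-passing network needs are implemented:
dense affine maps, ReLU, elementwise arithmetic, concatenation, row
gather/scatter (segment sums over graph edges and molecule segments),
softmax, and reductions. Tapes are define-by-run and rebuilt per batch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "gather", "relu", "softmax"]


class Tensor:
    """An array node on the tape.

    `requires_grad` marks leaves (parameters); intermediate nodes carry a
    closure that routes the upstream gradient to their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph walk ------------------------------------------------------

    def backward(self, grad=None):
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    # -- ops -------------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = _wrap(other)
        out_data = self.data - other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(-_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __mul__(self, other):
        other = _wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _wrap(other)
        out_data = self.data @ other.data

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    @property
    def T(self):
        out_data = self.data.T

        def bwd(g):
            self._accum(g.T)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def square(self):
        return self * self

    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(np.asarray(g).reshape(old))

        return Tensor(out_data, parents=(self,), backward=bwd)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce gradient `g` back to `shape` after NumPy broadcasting."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g):
        x._accum(g * mask)

    return Tensor(out_data, parents=(x,), backward=bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of `x`; backward scatter-adds into the source rows."""
    index = np.asarray(index, dtype=np.intp)
    out_data = x.data[index]

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, index, g)
        x._accum(acc)

    return Tensor(out_data, parents=(x,), backward=bwd)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets; backward is a gather."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, x.data)

    def bwd(g):
        x._accum(np.asarray(g)[segment_ids])

    return Tensor(out_data, parents=(x,), backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor(s, parents=(x,), backward=bwd)
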