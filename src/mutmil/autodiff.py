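"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical backbone for the MIL model: a taped ``Tensor`` type
with exactly the operations the bag model needs (dense algebra, the smooth
adaptive activations, ragged segment reductions) plus an Adam optimizer.
Everything runs in float64 on CPU, which keeps training bit-reproducible
for a fixed seed.

The ragged-bag contract lives here: a batch of variable-length bags is a
single instance-major matrix together with per-bag row counts, and all
bag-level reductions are segment-wise (`segment_sum`) with the inverse
broadcast (`repeat_rows`). No bag is ever padded to the max bag size.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "repeat_rows", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.array(data, dtype=np.float64), requires_grad=True)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, c: float):
        out = Tensor(self.data**c, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * c * self.data ** (c - 1.0))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = back
        return out

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = back
        return out

    def log1p(self):
        out = Tensor(np.log1p(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data))

        out._backward = back
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * 0.5 / val)

        out._backward = back
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = back
        return out

    # -- shape / indexing -----------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = back
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._backward = back
        return out

    def take(self, idx: np.ndarray) -> "Tensor":
        """Gather rows along axis 0 (embedding lookup / im2col gather)."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], (self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = back
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int):
        """Max over one axis; ties share the gradient equally."""
        val = self.data.max(axis=axis)
        out = Tensor(val, (self,))

        def back(g):
            if not self.requires_grad:
                return
            expanded = np.expand_dims(val, axis)
            mask = self.data == expanded
            counts = mask.sum(axis=axis, keepdims=True)
            self._accum(mask * np.expand_dims(g, axis) / counts)

        out._backward = back
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- backward pass --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tensors)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    out._backward = back
    return out


def segment_sum(x: Tensor, counts: np.ndarray) -> Tensor:
    """Sum contiguous row segments of an instance-major matrix.

    `counts[i]` is the number of rows belonging to bag i; rows are assumed
    grouped in bag order (the ragged-batch contract). Returns one row per bag.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() != x.data.shape[0]:
        raise ValueError("segment counts do not cover the instance rows")
    if (counts <= 0).any():
        raise ValueError("empty bag in segment reduction")
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    out = Tensor(np.add.reduceat(x.data, starts, axis=0), (x,))

    def back(g):
        if x.requires_grad:
            x._accum(np.repeat(g, counts, axis=0))

    out._backward = back
    return out


def repeat_rows(s: Tensor, counts: np.ndarray) -> Tensor:
    """Broadcast one row per bag back to that bag's instance rows."""
    counts = np.asarray(counts, dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    out = Tensor(np.repeat(s.data, counts, axis=0), (s,))

    def back(g):
        if s.requires_grad:
            s._accum(np.add.reduceat(g, starts, axis=0))

    out._backward = back
    return out


class Adam:
    """Adam with optional decoupled L2 handled by the loss, not the step."""

    def __init__(self, params: list[Tensor], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
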