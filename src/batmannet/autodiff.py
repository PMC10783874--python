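"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains its networks with plain NumPy, so this module provides the
small set of differentiable primitives the model needs: broadcasting
arithmetic, matmul (with stacked/batched operands of equal leading shape),
reshape/transpose, row gather/scatter, column slicing, concatenation, relu,
exp/log/pow, sigmoid, and reductions.  Gradients are accumulated by a
topological sweep from a scalar loss.

All tensors are float64.  The engine is deliberately eager and unfancy; its
correctness is pinned by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "relu", "exp",
           "log", "sigmoid", "softmax", "log_softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), backward=None, requires_grad=False, name=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in self._parents)
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        # iterative topological order (graphs can be deep)
        topo, visited, stack = [], set(), [(self, False)]
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
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** exponent, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, (self, other))
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                if b.ndim == 1:
                    self._accum(np.outer(g, b) if a.ndim > 1 else g * b)
                else:
                    gb = g[..., None, :] if g.ndim == b.ndim - 1 else g
                    self._accum(_unbroadcast(gb @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    other._accum(np.outer(a, g) if b.ndim > 1 else g * a)
                else:
                    gb = g[..., None, :] if g.ndim == a.ndim - 1 else g
                    other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ gb, b.shape))
        out._backward = bw
        return out

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bw
        return out

    def slice_cols(self, start: int, stop: int):
        out = Tensor(self.data[..., start:stop], (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[..., start:stop] = g
                self._accum(full)
        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ----------------------------------------------------------------- free ops
def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)
    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data), (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * out.data)
    out._backward = bw
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g / x.data)
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-x.data)), (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * out.data * (1.0 - out.data))
    out._backward = bw
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(s, e)
                t._accum(g[tuple(idx)])
    out._backward = bw
    return out


def gather_rows(x: Tensor, idx) -> Tensor:
    """Rows of a 2-D tensor selected by an integer index array."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(x.data[idx], (x,))

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, idx, g)
            x._accum(full)
    out._backward = bw
    return out


def segment_sum(x: Tensor, seg_ids, n_segments: int) -> Tensor:
    """out[s] = sum of rows i with seg_ids[i] == s.  Rows with no members are 0."""
    seg_ids = np.asarray(seg_ids, dtype=np.int64)
    data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, seg_ids, x.data)
    out = Tensor(data, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g[seg_ids])
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - x.data.max(axis=axis, keepdims=True)  # constant shift: safe
    e = exp(shift)
    return e * e.sum(axis=axis, keepdims=True) ** -1.0


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - x.data.max(axis=axis, keepdims=True)
    return shift - log(exp(shift).sum(axis=axis, keepdims=True))


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gain + bias
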