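"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable parts of the pipeline (temporal convolutional encoder,
projection heads, cross-modal attention, classifier) are small enough that a
compact tape-based engine over float64 numpy arrays is fast and exactly
reproducible on a single CPU.  Only the operations those modules need are
implemented: broadcasting arithmetic, matmul (batched), reductions, shape
ops, slicing/padding along the time axis, exp/log/sqrt and the ELU/ReLU
nonlinearities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g / other.data)
                if other.requires_grad:
                    other._accum(-g * self.data / other.data**2)
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(np.matmul(self.data, other.data), (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    if other.data.ndim == 1:
                        self._accum(np.multiply.outer(g, other.data)
                                    if g.ndim else g * other.data)
                    else:
                        self._accum(_unbroadcast(
                            np.matmul(g, np.swapaxes(other.data, -1, -2)),
                            self.data.shape))
                if other.requires_grad:
                    if self.data.ndim == 1:
                        other._accum(np.multiply.outer(self.data, g))
                    else:
                        other._accum(_unbroadcast(
                            np.matmul(np.swapaxes(self.data, -1, -2), g),
                            other.data.shape))
            out._backward = backward
        return out

    # -- pointwise nonlinearities ---------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        s = np.sqrt(self.data)
        out = self._make(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / s)
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        e = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = self._make(np.where(pos, self.data, e), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.where(pos, 1.0, e + alpha))
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = self._make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def swapaxes(self, a, b):
        out = self._make(np.swapaxes(self.data, a, b), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    def transpose_last(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        if out.requires_grad:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = backward
        return out

    def pad_time(self, left: int, axis: int = -2):
        """Zero-pad `left` steps at the start of the time axis."""
        pad = [(0, 0)] * self.data.ndim
        pad[axis] = (left, 0)
        out = self._make(np.pad(self.data, pad), (self,), None)
        if out.requires_grad:
            sl = [slice(None)] * self.data.ndim
            sl[axis] = slice(left, None)
            out._backward = lambda g: self._accum(g[tuple(sl)])
        return out

    # -- composites ------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self - self.data.max(axis=axis, keepdims=True)  # detached max
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def l2_normalize(self, axis=-1, eps=1e-12):
        norm = ((self * self).sum(axis=axis, keepdims=True) + eps).sqrt()
        return self / norm


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis=-1):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack_rows(tensors):
    """Stack 1-D/2-D tensors along a new leading axis."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors]))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        def backward(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(g[i])
        out._parents = tuple(tensors)
        out._backward = backward
    return out
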