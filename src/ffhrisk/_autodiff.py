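"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the regression architectures need: broadcast
arithmetic, 2-D matmul, slicing, reshape, padding, concatenation, ReLU /
sigmoid / tanh / abs, reductions and a max-along-axis with first-maximum
subgradient.  Graphs are built per sample (batch size 1 throughout), so the
engine favours low constant overhead over vectorised batching.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "max_along", "pad"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce grad back to `shape` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "_parents", "_back", "requires_grad")

    def __init__(self, data, parents=(), back=None, requires_grad=False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._back = back
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, back):
        out = Tensor(data, parents=parents)
        if out.requires_grad:
            out._back = back
        return out

    def _acc(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g, dtype=float)
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._acc(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(out.grad, other.data.shape))
        if out.requires_grad:
            out._back = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def back():
            self._acc(-out.grad)
        if out.requires_grad:
            out._back = back
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._acc(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(out.grad * self.data, other.data.shape))
        if out.requires_grad:
            out._back = back
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._acc(out.grad @ other.data.T)
            if other.requires_grad:
                other._acc(self.data.T @ out.grad)
        if out.requires_grad:
            out._back = back
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def back():
            g = np.zeros_like(self.data)
            g[idx] += out.grad
            self._acc(g)
        if out.requires_grad:
            out._back = back
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def back():
            self._acc(out.grad.reshape(self.data.shape))
        if out.requires_grad:
            out._back = back
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def back():
            self._acc(out.grad * mask)
        if out.requires_grad:
            out._back = back
        return out

    def sigmoid(self):
        s = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.clip(self.data, 0, None))),
                     np.exp(np.clip(self.data, None, 0))
                     / (1.0 + np.exp(np.clip(self.data, None, 0))))
        out = self._make(s, (self,), None)

        def back():
            self._acc(out.grad * s * (1.0 - s))
        if out.requires_grad:
            out._back = back
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,), None)

        def back():
            self._acc(out.grad * (1.0 - t * t))
        if out.requires_grad:
            out._back = back
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = self._make(np.abs(self.data), (self,), None)

        def back():
            self._acc(out.grad * sign)
        if out.requires_grad:
            out._back = back
        return out

    def square(self):
        return self * self

    # -- reductions -------------------------------------------------------
    def sum(self):
        out = self._make(self.data.sum(), (self,), None)

        def back():
            self._acc(np.full_like(self.data, out.grad))
        if out.requires_grad:
            out._back = back
        return out

    def mean(self):
        n = self.data.size
        out = self._make(self.data.mean(), (self,), None)

        def back():
            self._acc(np.full_like(self.data, out.grad / n))
        if out.requires_grad:
            out._back = back
        return out

    # -- autodiff ----------------------------------------------------------
    def backward(self):
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
            if node._back is not None:
                node._back()

    def zero_grad(self):
        self.grad = None


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))

    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * data.ndim
                sl[axis] = slice(lo, hi)
                t._acc(out.grad[tuple(sl)])
    if out.requires_grad:
        out._back = back
    return out


def max_along(x: Tensor, axis: int) -> Tensor:
    """Max over one axis; subgradient flows to the first maximum on ties."""
    idx = np.argmax(x.data, axis=axis)
    data = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)
    out = Tensor(data, parents=(x,))

    def back():
        g = np.zeros_like(x.data)
        np.put_along_axis(g, np.expand_dims(idx, axis),
                          np.expand_dims(out.grad, axis), axis=axis)
        x._acc(g)
    if out.requires_grad:
        out._back = back
    return out


def pad(x: Tensor, pad_width) -> Tensor:
    out = Tensor(np.pad(x.data, pad_width), parents=(x,))

    def back():
        sl = tuple(slice(lo, dim + lo) for (lo, _), dim in zip(pad_width, x.data.shape))
        x._acc(out.grad[sl])
    if out.requires_grad:
        out._back = back
    return out
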