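"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation through the
recorded graph. Broadcasting follows numpy semantics (gradients are
summed back over broadcast axes). This is deliberately a small engine:
just the ops the sequence models in :mod:`rehabkit.nn.layers` need.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (1 - y * y))

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * y * (1 - y))

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * y)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # -- reductions & shaping -------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def bw():
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accum(out.grad.transpose(inv))

        out._backward = bw
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice, type(Ellipsis))) for i in idx)
        )

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                if basic:
                    g[idx] += out.grad
                else:
                    np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = bw
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _prev=(self,))

        def bw():
            if self.requires_grad:
                dot = (out.grad * y).sum(axis=axis, keepdims=True)
                self._accum(y * (out.grad - dot))

        out._backward = bw
        return out


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw():
        gs = np.moveaxis(out.grad, axis, 0)
        for t, g in zip(tensors, gs):
            if t.requires_grad:
                t._accum(g)

    out._backward = bw
    return out
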