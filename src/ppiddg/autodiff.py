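"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the Siamese regressor: broadcast
arithmetic, matrix products, reductions, elementwise nonlinearities, a
numerically stable log-cosh, softmax and layer normalization.  Gradients
flow only into :class:`Tensor` leaves created with ``requires_grad=True``
(model parameters); all data inputs enter as constants, which keeps the
graph small and the implementation simple.

Verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.data))
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, n in enumerate(shape):
            if n == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g.reshape(shape)

    def _node(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(self._unbroadcast(g, self.shape))
            other._accumulate(self._unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(self._unbroadcast(g * other.data, self.shape))
            other._accumulate(self._unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(self._unbroadcast(g / other.data, self.shape))
            other._accumulate(
                self._unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._node(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                self._accumulate(g @ b.T)
                other._accumulate(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 2:
                self._accumulate(g @ b.T)
                other._accumulate(a.T @ g)
            elif a.ndim == 2 and b.ndim == 1:
                self._accumulate(np.outer(g, b))
                other._accumulate(a.T @ g)
            else:
                raise NotImplementedError("matmul backward for >2-d operands")

        return self._node(self.data @ other.data, (self, other), backward)

    def power(self, exponent: float):
        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._node(self.data**exponent, (self,), backward)

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None):
        def backward(g):
            if axis is None:
                self._accumulate(np.full_like(self.data, g))
            else:
                self._accumulate(np.broadcast_to(np.expand_dims(g, axis), self.shape).copy())

        return self._node(self.data.sum(axis=axis), (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g):
            self._accumulate(g.T)

        return self._node(self.data.T, (self,), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._node(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return self._node(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._node(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return self._node(np.abs(self.data), (self,), backward)

    def logcosh(self):
        """Numerically stable log cosh: |x| + log1p(e^(-2|x|)) - log 2."""
        x = self.data
        out_data = np.maximum(
            0.0, np.abs(x) + np.log1p(np.exp(-2.0 * np.abs(x))) - np.log(2.0))

        def backward(g):
            self._accumulate(g * np.tanh(x))

        return self._node(out_data, (self,), backward)

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return self._node(out_data, (self,), backward)

    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean and unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv
        n = self.data.shape[-1]

        def backward(g):
            gm = g - g.mean(axis=-1, keepdims=True)
            proj = (g * out_data).mean(axis=-1, keepdims=True)
            self._accumulate(inv * (gm - out_data * proj))
            _ = n

        return self._node(out_data, (self,), backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate 1-d tensors."""
    sizes = [t.data.size for t in tensors]
    out = Tensor(np.concatenate([t.data.reshape(-1) for t in tensors]))
    if any(t.requires_grad or t._parents for t in tensors):
        out._parents = tuple(tensors)

        def backward(g):
            offset = 0
            for t, size in zip(tensors, sizes):
                t._accumulate(g[offset:offset + size].reshape(t.shape))
                offset += size

        out._backward = backward
    return out


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
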