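"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective couples a neural network to several geometric
quantities (density-weighted coordinate averages, pairwise-distance
matrices, a molecular-mechanics potential), so gradients must flow through
arbitrary compositions of array operations.  This module provides a small
vectorized tape: a :class:`Tensor` wraps an ``ndarray``, records the
operations applied to it, and :meth:`Tensor.backward` accumulates
gradients by reverse topological traversal.

Only the operations the package actually uses are implemented.  All
operations support numpy broadcasting; gradients are un-broadcast
(summed) back to the operand shapes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "softplus",
    "arccos",
    "cos",
    "maximum0",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind != "f" else None)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument requires a scalar Tensor")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        # topological order
        order, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g
        # self may itself be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = grad

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._op(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._op(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._op(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._op(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        return Tensor._op(
            a.data**p,
            (a,),
            lambda g: (g * p * a.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        if a.data.ndim < 2 or b.data.ndim < 2:
            raise ValueError("matmul requires >=2-D operands")

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

        return Tensor._op(a.data @ b.data, (a, b), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g2, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._op(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def transpose(self, *axes):
        a = self
        axes = axes or None
        if axes is not None and len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = None if axes is None else tuple(np.argsort(axes))
        return Tensor._op(
            a.data.transpose(axes),
            (a,),
            lambda g: (g.transpose(inv),),
        )

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._op(a.data[idx], (a,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions ----------------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.exp(x.data)
    return Tensor._op(out_data, (x,), lambda g: (g * out_data,))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._op(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.sqrt(x.data)
    return Tensor._op(out_data, (x,), lambda g: (g * 0.5 / out_data,))


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)
    return Tensor._op(out_data, (x,), lambda g: (g * (1.0 - out_data**2),))


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; maps reals to positive values."""
    x = as_tensor(x)
    out_data = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._op(out_data, (x,), lambda g: (g * sig,))


def cos(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._op(np.cos(x.data), (x,), lambda g: (-g * np.sin(x.data),))


def arccos(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._op(
        np.arccos(np.clip(x.data, -1.0, 1.0)),
        (x,),
        lambda g: (-g / np.sqrt(np.maximum(1.0 - x.data**2, 1e-300)),),
    )


def maximum0(x: Tensor) -> Tensor:
    """ReLU."""
    x = as_tensor(x)
    mask = x.data > 0
    return Tensor._op(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
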