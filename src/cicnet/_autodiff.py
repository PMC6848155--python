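"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the autoencoder forward passes and
objectives need: broadcasting elementwise arithmetic, (batched) matrix
multiplication, the activation functions searched over by the
architecture space, reductions, and a few compositions (softmax,
batch statistics).  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward` over a topologically sorted graph.

Broadcasting is handled by summing gradients over broadcast axes, so
parameters of any shape can enter batched expressions directly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "relu",
    "softplus",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "softmax",
    "matmul",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were added or broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were prepended
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (must be scalar if ``grad`` is None)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not (node.requires_grad or node._parents):
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not (parent.requires_grad or parent._parents):
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic ----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def back(g):
            return ((self, _unbroadcast(g, self.shape)), (other, _unbroadcast(g, other.shape)))

        return Tensor(self.data + other.data, parents=(self, other), backward=back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            return ((self, -g),)

        return Tensor(-self.data, parents=(self,), backward=back)

    def __sub__(self, other):
        other = self._coerce(other)

        def back(g):
            return ((self, _unbroadcast(g, self.shape)), (other, _unbroadcast(-g, other.shape)))

        return Tensor(self.data - other.data, parents=(self, other), backward=back)

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        other = self._coerce(other)

        def back(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return Tensor(self.data * other.data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def back(g):
            return (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            )

        return Tensor(self.data / other.data, parents=(self, other), backward=back)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def back(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor(self.data**p, parents=(self,), backward=back)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return Tensor(out, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.shape

        def back(g):
            return ((self, g.reshape(old)),)

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=back)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def back(g):
            return ((self, g.transpose(inv)),)

        return Tensor(self.data.transpose(axes), parents=(self,), backward=back)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


# -- nonlinearities ----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        return ((x, g * mask),)

    return Tensor(x.data * mask, parents=(x,), backward=back)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def back(g):
        return ((x, g * s * (1.0 - s)),)

    return Tensor(s, parents=(x,), backward=back)


def softplus(x: Tensor) -> Tensor:
    # log(1+e^x) computed stably; derivative is the logistic function
    out = np.logaddexp(0.0, x.data)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def back(g):
        return ((x, g * s),)

    return Tensor(out, parents=(x,), backward=back)


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)

    def back(g):
        return ((x, g * e),)

    return Tensor(e, parents=(x,), backward=back)


def log(x: Tensor) -> Tensor:
    def back(g):
        return ((x, g / x.data),)

    return Tensor(np.log(x.data), parents=(x,), backward=back)


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)

    def back(g):
        return ((x, g * 0.5 / r),)

    return Tensor(r, parents=(x,), backward=back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stochastic softmax (stabilised by a detached max shift)."""
    shift = constant(x.data.max(axis=axis, keepdims=True))
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batching semantics (leading axes broadcast)."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    out = np.matmul(a.data, b.data)

    def back(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

    return Tensor(out, parents=(a, b), backward=back)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor(out, parents=tuple(tensors), backward=back)
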