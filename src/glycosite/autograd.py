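"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This engine exists to back-propagate through the geometric transformer and
its training loop.  It implements exactly the operator set the network
needs — broadcast arithmetic, matmul, gather, softmax, concatenation,
reductions and a handful of nonlinearities — as a dynamically built tape of
:class:`Tensor` nodes, plus an Adam optimizer.

All arithmetic is float64.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward`, which walks the tape in reverse topological
order.  Broadcasting in the forward pass is undone in the backward pass by
summing gradients over broadcast axes (:func:`_unbroadcast`).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concatenate", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to produce it."""
    if grad.shape == shape:
        return grad
    # collapse leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _node(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: the tape can be thousands of nodes deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._node(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return self._node(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        y = np.exp(self.data)

        def backward(g):
            self._accumulate(g * y)

        return self._node(y, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        y = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / y)

        return self._node(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * y * (1.0 - y))

        return self._node(y, (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        y = np.where(pos, self.data, alpha * np.expm1(np.minimum(self.data, 0.0)))

        def backward(g):
            self._accumulate(g * np.where(pos, 1.0, y + alpha))

        return self._node(y, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the bounds."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accumulate(g * inside)

        return self._node(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._node(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accumulate(np.swapaxes(g, a, b))

        return self._node(np.swapaxes(self.data, a, b), (self,), backward)

    def take(self, idx: np.ndarray):
        """Gather rows along axis 0; ``idx`` may have any shape."""
        idx = np.asarray(idx)

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx.ravel(), g.reshape(-1, *self.data.shape[1:]))
            self._accumulate(acc)

        return self._node(self.data[idx], (self,), backward)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    return Tensor._node(y, (x,), backward)


class Adam:
    """Adaptive moment estimation optimizer (bias-corrected first/second moments)."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
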