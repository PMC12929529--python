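"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The classifier heads in this package are small (a few hundred thousand
parameters at most, trained with batch size 1), so instead of depending on a
deep-learning framework the package carries its own tensor type: a thin
wrapper around ``numpy.ndarray`` that records the computation graph and
back-propagates gradients through the handful of operations the models need
(affine maps, tanh/sigmoid/ReLU gates, softmax attention, outer products,
concatenation, dropout masks and the binary cross-entropy objective).

Gradients for broadcast operands are reduced back to the operand's shape, so
bias vectors and scalar scalings behave as expected.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad=None) -> None:
        """Back-propagate from this tensor (must be scalar if grad omitted)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def backward(g):
            g = np.asarray(g)
            if self.requires_grad:
                if a.ndim == 2 and b.ndim == 2:
                    self._accumulate(g @ b.T)
                elif a.ndim == 2:  # b 1-d, g (m,)
                    self._accumulate(np.outer(g, b))
                elif b.ndim == 2:  # a 1-d, g (n,)
                    self._accumulate(b @ g)
                else:  # both 1-d, g scalar
                    self._accumulate(g * b)
            if other.requires_grad:
                if a.ndim == 2 and b.ndim == 2:
                    other._accumulate(a.T @ g)
                elif a.ndim == 2:  # g (m,)
                    other._accumulate(a.T @ g)
                elif b.ndim == 2:  # g (n,)
                    other._accumulate(np.outer(a, g))
                else:
                    other._accumulate(g * a)

        return self._make(a @ b, (self, other), backward)

    # -- nonlinearities -----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - y * y))

        return self._make(y, (self,), backward)

    def sigmoid(self):
        # stable logistic: never exponentiates a large positive argument
        e = np.exp(-np.abs(self.data))
        y = np.where(self.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

        def backward(g):
            self._accumulate(g * y * (1.0 - y))

        return self._make(y, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softmax(self):
        """Softmax over the last axis, computed with max-subtraction."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            self._accumulate(y * (g - dot))

        return self._make(y, (self,), backward)

    def logaddexp0(self):
        """log(1 + exp(x)) elementwise (softplus), stable for large |x|."""
        y = np.logaddexp(0.0, self.data)
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -700, 700)))

        def backward(g):
            self._accumulate(g * s)

        return self._make(y, (self,), backward)

    # -- reductions and shaping ----------------------------------------------

    def sum(self):
        def backward(g):
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            self._accumulate(np.broadcast_to(g / n, self.data.shape).copy())

        return self._make(self.data.mean(), (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accumulate(np.asarray(g).reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def outer(self, other: "Tensor"):
        """Outer product of two 1-d tensors."""
        other = self._lift(other)
        a, b = self.data, other.data
        if a.ndim != 1 or b.ndim != 1:
            raise ValueError("outer() requires 1-d tensors")

        def backward(g):
            g = np.asarray(g)
            if self.requires_grad:
                self._accumulate(g @ b)
            if other.requires_grad:
                other._accumulate(a @ g)

        return self._make(np.outer(a, b), (self, other), backward)

    # -- misc ----------------------------------------------------------------

    def dropout(self, rate: float, rng: np.random.Generator, training: bool):
        """Inverted dropout; identity when not training or rate == 0."""
        if not training or rate <= 0.0:
            return self
        keep = rng.random(self.data.shape) >= rate
        scale = keep / (1.0 - rate)

        def backward(g):
            self._accumulate(g * scale)

        return self._make(self.data * scale, (self,), backward)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate 1-d tensors, propagating gradients to each slice."""
    datas = [t.data for t in tensors]
    if any(d.ndim != 1 for d in datas):
        raise ValueError("concat() requires 1-d tensors")
    sizes = [d.size for d in datas]
    offsets = np.cumsum([0] + sizes)
    out = Tensor(np.concatenate(datas))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    t._accumulate(np.asarray(g)[lo:hi])

        out._backward = backward
    return out
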