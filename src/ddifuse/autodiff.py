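"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine supporting exactly the operations the fusion network
needs: affine maps, sparse-dense propagation, ReLU/tanh/sigmoid, elementwise
arithmetic with broadcasting, row gathering, concatenation, reductions and a
numerically stable log-softmax.  Gradients are accumulated by topological
traversal of the expression graph; correctness is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor", "relu", "tanh", "sigmoid", "absolute", "log_softmax",
    "concat", "row_normalize", "spmm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, reversing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("value", "grad", "requires_grad", "_parents")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, vjp: grad_out -> grad_parent)
        self._parents: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = []

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, value, parents) -> "Tensor":
        out = Tensor(value)
        out._parents = [(p, fn) for p, fn in parents if p.requires_grad or p._parents]
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        return self._make(
            self.value + other.value,
            [
                (self, lambda g: _unbroadcast(g, self.value.shape)),
                (other, lambda g: _unbroadcast(g, other.value.shape)),
            ],
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)
        return self._make(
            self.value - other.value,
            [
                (self, lambda g: _unbroadcast(g, self.value.shape)),
                (other, lambda g: _unbroadcast(-g, other.value.shape)),
            ],
        )

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)
        return self._make(
            self.value * other.value,
            [
                (self, lambda g: _unbroadcast(g * other.value, self.value.shape)),
                (other, lambda g: _unbroadcast(g * self.value, other.value.shape)),
            ],
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self._make(-self.value, [(self, lambda g: -g)])

    def __matmul__(self, other):
        other = self._lift(other)
        return self._make(
            self.value @ other.value,
            [
                (self, lambda g: g @ other.value.T),
                (other, lambda g: self.value.T @ g),
            ],
        )

    def __pow__(self, p: float):
        if p != 2:
            raise NotImplementedError("only squaring is needed")
        return self * self

    # -- shaping ------------------------------------------------------------

    @property
    def T(self) -> "Tensor":
        return self._make(self.value.T, [(self, lambda g: g.T)])

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.int64)

        def vjp(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return out

        return self._make(self.value[idx], [(self, vjp)])

    def reshape(self, *shape) -> "Tensor":
        old = self.value.shape
        return self._make(self.value.reshape(*shape), [(self, lambda g: g.reshape(old))])

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.value.shape).copy()
            gg = np.expand_dims(g, axis) if not keepdims else g
            return np.broadcast_to(gg, self.value.shape).copy()

        return self._make(self.value.sum(axis=axis, keepdims=keepdims), [(self, vjp)])

    def mean(self) -> "Tensor":
        n = self.value.size
        return self.sum() * (1.0 / n)

    # -- backward pass ------------------------------------------------------

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, parents = stack[-1]
                advanced = False
                for parent, _ in parents:
                    if id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.value)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node._parents:
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# ---------------------------------------------------------------------------
# functional ops


def relu(t: Tensor) -> Tensor:
    mask = t.value > 0
    return t._make(np.where(mask, t.value, 0.0), [(t, lambda g: g * mask)])


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.value)
    return t._make(y, [(t, lambda g: g * (1.0 - y * y))])


def sigmoid(t: Tensor) -> Tensor:
    y = 0.5 * (np.tanh(0.5 * t.value) + 1.0)  # stable logistic
    return t._make(y, [(t, lambda g: g * y * (1.0 - y))])


def absolute(t: Tensor) -> Tensor:
    s = np.sign(t.value)  # subgradient 0 at the kink
    return t._make(np.abs(t.value), [(t, lambda g: g * s)])


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along `axis`."""
    x = t.value
    m = x.max(axis=axis, keepdims=True)
    shifted = x - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    y = shifted - lse
    softmax = np.exp(y)

    def vjp(g):
        return g - softmax * g.sum(axis=axis, keepdims=True)

    return t._make(y, [(t, vjp)])


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    value = np.concatenate([t.value for t in tensors], axis=axis)

    def make_vjp(k):
        sl = [slice(None)] * value.ndim
        sl[axis] = slice(offsets[k], offsets[k + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    out = tensors[0]._make(value, [(t, make_vjp(k)) for k, t in enumerate(tensors)])
    return out


def row_normalize(t: Tensor, eps: float = 1e-12) -> Tensor:
    """Scale each row to unit L2 norm (zero rows stay ~zero)."""
    x = t.value
    n = np.sqrt((x * x).sum(axis=1, keepdims=True) + eps)
    y = x / n

    def vjp(g):
        return g / n - x * ((g * x).sum(axis=1, keepdims=True) / n**3)

    return t._make(y, [(t, vjp)])


def spmm(A: sp.spmatrix, t: Tensor) -> Tensor:
    """Sparse-constant @ dense-tensor product (the GCN propagation step)."""
    AT = A.T.tocsr()
    return t._make(A @ t.value, [(t, lambda g: AT @ g)])
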