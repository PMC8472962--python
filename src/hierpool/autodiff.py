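"""Reverse-mode automatic differentiation on dense numpy arrays.

A small tape-based engine covering exactly the operations the pooling
networks in this package need: dense matrix products, broadcasting
arithmetic, ReLU, reductions, concatenation and the row softmax family.
Every differentiable value is a :class:`Tensor`; calling ``backward()``
on a scalar result accumulates gradients into the leaf tensors that
were created with ``requires_grad=True``.

Gradients for leaves accumulate across repeated ``backward()`` calls,
which is how mini-batches of variable-size graphs are handled (one
forward/backward per graph, then a single optimiser step).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "transpose",
    "reshape",
    "relu",
    "exp",
    "log",
    "sqrt",
    "xlogx",
    "tsum",
    "concat",
    "softmax_rows",
    "log_softmax_rows",
    "Adam",
]


class Tensor:
    """A dense float64 array plus the tape bookkeeping for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # materialise: g may be a broadcast view
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Backpropagate from this (scalar) tensor into all leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(_topo_order(self)):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                t.grad = None  # free intermediates; leaves keep theirs

    # -- conveniences --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        return tsum(self, axis=axis, keepdims=keepdims)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def _node(data: np.ndarray, parents: Iterable, backward) -> Tensor:
    out = Tensor(data)
    grad_parents = tuple(
        p for p in parents if isinstance(p, Tensor) and p.requires_grad
    )
    if grad_parents:
        out.requires_grad = True
        out._parents = grad_parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise arithmetic -------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.data.shape))

    return _node(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _node(a.data / b.data, (a, b), backward)


# -- linear algebra ----------------------------------------------------


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul expects 2-D operands; reshape vectors first")

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), backward)


def transpose(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accum(g.T)

    return _node(a.data.T, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return _node(a.data.reshape(shape), (a,), backward)


# -- nonlinearities and reductions ------------------------------------


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accum(g * mask)

    return _node(np.where(mask, a.data, 0.0), (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accum(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)
    # subgradient 0 at the origin so degenerate all-zero matrices are inert
    safe = np.where(out_data > 0, out_data, 1.0)

    def backward(g):
        a._accum(np.where(out_data > 0, g * 0.5 / safe, 0.0))

    return _node(out_data, (a,), backward)


def xlogx(a) -> Tensor:
    """Elementwise x*ln(x) with the entropy convention 0*ln(0) = 0."""
    a = as_tensor(a)
    pos = a.data > 0
    safe = np.where(pos, a.data, 1.0)
    logs = np.log(safe)

    def backward(g):
        a._accum(np.where(pos, g * (logs + 1.0), 0.0))

    return _node(np.where(pos, a.data * logs, 0.0), (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def concat(parts: Sequence) -> Tensor:
    """Concatenate tensors (flattened) into one 1-D tensor."""
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.size for p in parts]

    def backward(g):
        offset = 0
        for p, size in zip(parts, sizes):
            if p.requires_grad:
                p._accum(g[offset : offset + size].reshape(p.data.shape))
            offset += size

    return _node(
        np.concatenate([p.data.ravel() for p in parts]), tuple(parts), backward
    )


# -- softmax family ----------------------------------------------------


def softmax_rows(a) -> Tensor:
    """Numerically stable row softmax (per-row max subtracted)."""
    a = as_tensor(a)
    shift = a - a.data.max(axis=-1, keepdims=True)  # constant shift: exact grads
    e = exp(shift)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax_rows(a) -> Tensor:
    a = as_tensor(a)
    shift = a - a.data.max(axis=-1, keepdims=True)
    return shift - log(exp(shift).sum(axis=-1, keepdims=True))


# -- optimisation ------------------------------------------------------


class Adam:
    """Adaptive-moment gradient descent over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * p.grad
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
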