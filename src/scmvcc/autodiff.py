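"""Minimal reverse-mode automatic differentiation over dense numpy arrays.

The training objective couples a two-layer graph convolutional encoder with
three contrastive loss families, so its gradient is impractical to derive and
maintain by hand.  This module provides the small operator set that objective
needs (matrix products, elementwise arithmetic with broadcasting, ReLU,
exp/log, axis reductions) as a tape-free dynamic graph: each operation stores
its parents and a vector-Jacobian closure, and :meth:`Tensor.backward`
accumulates gradients in reverse topological order.

Everything is float64 and CPU-only, which makes runs bit-reproducible for a
fixed seed.  Correctness is exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "matmul", "relu", "exp", "log", "tsum", "transpose"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _vjp: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._vjp = _vjp

    # -- graph construction helpers -------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar output; fills .grad on leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit recursion limits
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    # -- operators -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def vjp(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _vjp=vjp)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def vjp(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _vjp=vjp)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def vjp(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _vjp=vjp)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def vjp(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, other)

    @property
    def T(self) -> "Tensor":
        return transpose(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(a.data @ b.data, _parents=(a, b), _vjp=vjp)


def transpose(a: Tensor) -> Tensor:
    a = _as_tensor(a)

    def vjp(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g.T)

    return Tensor(a.data.T, _parents=(a,), _vjp=vjp)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def vjp(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(np.where(mask, a.data, 0.0), _parents=(a,), _vjp=vjp)


def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def vjp(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor(out_data, _parents=(a,), _vjp=vjp)


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)

    def vjp(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor(np.log(a.data), _parents=(a,), _vjp=vjp)


def tsum(a: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)

    def vjp(g: np.ndarray) -> None:
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.shape))

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,), _vjp=vjp)
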