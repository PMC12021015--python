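"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is a small tape-based engine: every operation builds a node that
remembers its parents and a closure that routes the output gradient back to
them.  It supports exactly the primitives the stability network needs —
dense and (constant) sparse matrix products, broadcast addition, elementwise
arithmetic, ReLU, row-wise layer and L2 normalisation, dropout masks and
reductions.  All computation is float64 and fully deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "matmul",
    "spmm",
    "add",
    "sub",
    "mul",
    "relu",
    "tanh",
    "concat_cols",
    "layer_norm_rows",
    "l2_normalize_rows",
    "mean_all",
    "square",
    "scale",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        value: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def accumulate(self, g: np.ndarray, fresh: bool = False) -> None:
        """Add `g` to the gradient; `fresh=True` marks a newly allocated array
        that may be adopted without copying."""
        if self.grad is None:
            self.grad = g if fresh else np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the whole tape."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order; deep tapes must not hit the recursion limit
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value) if seed is None else np.asarray(seed, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Small operator sugar used by the network code.
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return sub(self, other)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return matmul(self, other)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value + b.value

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value - b.value

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(-_unbroadcast(g, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value * b.value

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.value, a.value.shape), fresh=True)
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.value, b.value.shape), fresh=True)

    return Tensor(out_val, parents=(a, b), backward=backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * c, fresh=True)

    return Tensor(a.value * c, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value @ b.value

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g @ b.value.T, fresh=True)
        if b.requires_grad:
            b.accumulate(a.value.T @ g, fresh=True)

    return Tensor(out_val, parents=(a, b), backward=backward)


def spmm(s: sp.spmatrix, a: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a differentiable dense tensor."""
    s = s.tocsr()
    out_val = s @ a.value
    st = None

    def backward(g: np.ndarray) -> None:
        nonlocal st
        if a.requires_grad:
            if st is None:
                st = s.T.tocsr()
            a.accumulate(st @ g, fresh=True)

    return Tensor(out_val, parents=(a,), backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0.0
    out_val = np.maximum(a.value, 0.0)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * mask, fresh=True)

    return Tensor(out_val, parents=(a,), backward=backward)


def tanh(a: Tensor) -> Tensor:
    out_val = np.tanh(a.value)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * (1.0 - out_val**2))

    return Tensor(out_val, parents=(a,), backward=backward)


def identity(a: Tensor) -> Tensor:
    return a


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    na = a.value.shape[1]
    out_val = np.concatenate([a.value, b.value], axis=1)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g[:, :na])
        if b.requires_grad:
            b.accumulate(g[:, na:])

    return Tensor(out_val, parents=(a, b), backward=backward)


def layer_norm_rows(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the feature axis of an (N, H) tensor."""
    mu = x.value.mean(axis=1, keepdims=True)
    xc = x.value - mu
    var = (xc**2).mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_val = xhat * gain.value + bias.value

    def backward(g: np.ndarray) -> None:
        if gain.requires_grad:
            gain.accumulate(_unbroadcast(g * xhat, gain.value.shape))
        if bias.requires_grad:
            bias.accumulate(_unbroadcast(g, bias.value.shape))
        if x.requires_grad:
            gh = g * gain.value  # dL/dxhat
            h = x.value.shape[1]
            # standard layer-norm backward over the row axis
            dx = (
                gh - gh.mean(axis=1, keepdims=True) - xhat * (gh * xhat).mean(axis=1, keepdims=True)
            ) * inv
            del h
            x.accumulate(dx, fresh=True)

    return Tensor(out_val, parents=(x, gain, bias), backward=backward)


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Scale each row to unit L2 norm; all-zero rows are left at zero."""
    norms = np.sqrt(np.einsum("ij,ij->i", x.value, x.value))[:, None]
    safe = np.where(norms > eps, norms, 1.0)
    out_val = x.value / safe

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * out_val).sum(axis=1, keepdims=True)
            x.accumulate((g - out_val * dot) / safe, fresh=True)

    return Tensor(out_val, parents=(x,), backward=backward)


def mean_all(a: Tensor) -> Tensor:
    n = a.value.size

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(np.full(a.value.shape, float(g) / n))

    return Tensor(a.value.mean(), parents=(a,), backward=backward)


def square(a: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(2.0 * g * a.value, fresh=True)

    return Tensor(a.value**2, parents=(a,), backward=backward)


def numerical_gradient(
    f: Callable[[Iterable[np.ndarray]], float], arrays: list[np.ndarray], eps: float = 1e-6
) -> list[np.ndarray]:
    """Central finite differences of a scalar function; test oracle only."""
    grads = []
    for k, arr in enumerate(arrays):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            fp = f(arrays)
            arr[idx] = orig - eps
            fm = f(arrays)
            arr[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
        grads.append(g)
    return grads
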