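"""Minimal reverse-mode autodiff on NumPy arrays.

Only the operations needed by the reconstruction network are implemented:
dense/conv linear algebra, the activation zoo, batch norm, pooling and
shape surgery.  A ``Tensor`` records its parents and a backward closure;
``Tensor.backward()`` runs reverse topological accumulation.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "no_grad"]


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (inference)."""

    def __enter__(self):
        self.prev = _GradMode.enabled
        _GradMode.enabled = False

    def __exit__(self, *exc):
        _GradMode.enabled = self.prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GradMode.enabled
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph machinery ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _lift(x, dtype=None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        # keep scalar constants from upcasting a float32 graph
        if dtype is not None and arr.ndim == 0 and arr.dtype != dtype:
            arr = arr.astype(dtype)
        return Tensor(arr)

    def _make(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=rg, parents=tuple(p for p in parents if p.requires_grad), backward=backward if rg else None)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other, self.data.dtype)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other, self.data.dtype))

    def __rsub__(self, other):
        return self._lift(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.data.dtype)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other, self.data.dtype)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), bw)

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), bw)

    __matmul__ = matmul

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), bw)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def leaky_relu(self, alpha: float = 0.2):
        dt = self.data.dtype.type
        factor = np.where(self.data > 0, dt(1.0), dt(alpha))

        def bw(g):
            if self.requires_grad:
                self._accum(g * factor)

        return self._make(self.data * factor, (self,), bw)

    def elu(self, alpha: float = 1.0):
        neg = self.data <= 0
        expm1 = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(neg, expm1, self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(neg, expm1 + alpha, 1.0))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            if self.requires_grad:
                self._accum(g * sig)

        return self._make(out_data, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._make(e, (self,), bw)


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    rg = any(t.requires_grad for t in tensors)
    return Tensor(
        out_data,
        requires_grad=rg,
        parents=tuple(t for t in tensors if t.requires_grad),
        backward=bw if rg else None,
    )
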