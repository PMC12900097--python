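"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each :class:`Tensor` records its parents and a
closure that propagates gradients to them. :meth:`Tensor.backward` walks the
graph in reverse topological order. Only the operations needed by the
segmentation network are provided; everything is float32 end to end.
"""
from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Iterable["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients/graph as we go
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def _accumulate_at(self, idx, grad: np.ndarray) -> None:
        """Accumulate into a sub-block of the gradient (weight slices)."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[idx] += grad

    # -- elementary ops -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (p for p in (self, other) if p.requires_grad))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(-self.data)
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (p for p in (self, other) if p.requires_grad))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product (np.matmul semantics on the last two axes)."""
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.matmul(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (p for p in (self, other) if p.requires_grad))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        inv = np.argsort(axes)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def sum(self) -> "Tensor":
        out_data = self.data.sum(dtype=np.float32)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.shape))
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out_data = np.float32(self.data.mean(dtype=np.float64))
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g / n, self.shape).astype(np.float32))
        return out
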