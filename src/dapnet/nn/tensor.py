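"""Minimal reverse-mode autodiff over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for each produced value,
a closure that routes the upstream gradient to its parents.  ``backward()``
walks the recorded graph in reverse topological order.  Only the operations
needed by the model zoo are implemented; everything is dense NumPy, so BLAS
does the heavy lifting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True) if g.dtype != self.data.dtype else g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.data.dtype)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.data.dtype)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.data.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other, self.data.dtype) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor(out_data, True, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other, self.data.dtype)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, True, (self, other), bw)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        src_shape = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(src_shape))

        return Tensor(out_data, True, (self,), bw)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, True, (self,), bw)

    def transpose_last(self):
        """Transpose the last two axes (batched matrix transpose)."""
        return self.swapaxes(-1, -2)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        src_shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, src_shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, src_shape).copy())

        return Tensor(out_data, True, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for a in axes:
                n *= self.data.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def diagonal_last(self):
        """Diagonal of the last two axes: [..., d, d] -> [..., d]."""
        out_data = np.diagonal(self.data, axis1=-2, axis2=-1).copy()
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        src_shape = self.data.shape

        def bw(g):
            gg = np.zeros(src_shape, dtype=g.dtype)
            idx = np.arange(src_shape[-1])
            gg[..., idx, idx] = g
            self._accumulate(gg)

        return Tensor(out_data, True, (self,), bw)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(out_data, True, (self,), bw)

    def sigmoid(self):
        out_data = _sigmoid(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), bw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(x, dtype=np.float32) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))
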