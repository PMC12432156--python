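"""Compact reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the model zoo needs: broadcasting
elementwise arithmetic, (batched) matrix products, reductions with axes,
ReLU/exp/log/sqrt/tanh, numerically stable log-sum-exp, concatenation,
reshaping and basic indexing.  Gradients are accumulated by topological
sweep over the recorded tape.

Design notes
------------
* A :class:`Tensor` wraps a float64 ndarray.  ``requires_grad`` marks
  leaves that should accumulate ``.grad``; interior nodes propagate
  automatically.
* Broadcasting is undone in the backward pass by summing the gradient
  over broadcast axes (``_unbroadcast``).
* There is no implicit graph retention: calling :meth:`Tensor.backward`
  walks the graph once.  Build a fresh graph per training step.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (evaluation mode)."""

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
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = False
        return out

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data + b.data, (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data * b.data, (a, b),
            lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data / b.data, (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: (g * p * a.data ** (p - 1),)
        )

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)

        def backward(g):
            ad, bd = a.data, b.data
            if ad.ndim == 1 and bd.ndim == 1:  # inner product
                return g * bd, g * ad
            if ad.ndim == 1:
                ga = (g[..., None, :] * np.swapaxes(bd, -1, -2)).sum(-1)
                gb = ad[:, None] * g[..., None, :] if bd.ndim == 2 else None
                if bd.ndim > 2:
                    gb = np.matmul(ad[:, None], g[..., None, :])
                return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)
            if bd.ndim == 1:
                ga = g[..., :, None] * bd
                gb = np.matmul(np.swapaxes(ad, -1, -2), g[..., :, None])[..., 0]
                return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)
            ga = np.matmul(g, np.swapaxes(bd, -1, -2))
            gb = np.matmul(np.swapaxes(ad, -1, -2), g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * 0.5 / np.maximum(out_data, 1e-300),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * (1.0 - out_data ** 2),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: (g * out_data * (1 - out_data),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis=-1, keepdims=False):
        a = self
        m = np.max(a.data, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)  # all -inf slices -> lse = -inf
        ex = np.exp(a.data - m)
        s = ex.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        soft = ex / s

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (gg * soft,)

        res = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._make(res, (a,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),)
        )

    def swapaxes(self, ax1, ax2):
        a = self
        return Tensor._make(
            np.swapaxes(a.data, ax1, ax2), (a,), lambda g: (np.swapaxes(g, ax1, ax2),)
        )

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            return (ga,)

        return Tensor._make(a.data[idx], (a,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, False)]
            while stack:
                t, done = stack.pop()
                if done:
                    topo.append(t)
                    continue
                if id(t) in seen:
                    continue
                seen.add(id(t))
                stack.append((t, True))
                for p in t._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not (p.requires_grad or p._parents):
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offs = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offs[i], offs[i + 1]), axis=axis) for i in range(len(ts))
        )

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), backward)
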