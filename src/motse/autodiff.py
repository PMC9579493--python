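"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the graph-convolutional task
models: dense/sparse matrix products, broadcast bias addition, elementwise
nonlinearities, and segment reductions for graph readout. Gradients are
exact (no numerical approximation), which is what makes Gradient*Input
attribution well defined downstream.

All arrays are float64. The tape is built eagerly; calling
:meth:`Tensor.backward` on a scalar (or with an explicit seed gradient)
accumulates ``.grad`` on every reachable tensor with ``requires_grad``.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

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
    "sigmoid",
    "concat",
    "segment_sum",
    "segment_max",
    "total_sum",
    "mean_square",
    "bce_with_logits",
]


class Tensor:
    """A node in the computation graph wrapping an ndarray value."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    @property
    def shape(self):
        return self.value.shape

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate gradients of this tensor w.r.t. all ancestors."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.value)
        # topological order (iterative DFS; tapes here are small)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.value.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value @ b.value

    def bwd(g):
        _accum(a, g @ b.value.T)
        _accum(b, a.value.T @ g)

    return Tensor(out_val, _parents=(a, b), _backward=bwd)


def spmm(s: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse (constant) @ dense (differentiable)."""
    x = _as_tensor(x)
    s = s.tocsr()
    st = s.T.tocsr()
    out_val = s @ x.value

    def bwd(g):
        _accum(x, st @ g)

    return Tensor(out_val, _parents=(x,), _backward=bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value + b.value

    def bwd(g):
        _accum(a, _unbroadcast(g, a.value.shape))
        _accum(b, _unbroadcast(g, b.value.shape))

    return Tensor(out_val, _parents=(a, b), _backward=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value - b.value

    def bwd(g):
        _accum(a, _unbroadcast(g, a.value.shape))
        _accum(b, _unbroadcast(-g, b.value.shape))

    return Tensor(out_val, _parents=(a, b), _backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value * b.value

    def bwd(g):
        _accum(a, _unbroadcast(g * b.value, a.value.shape))
        _accum(b, _unbroadcast(g * a.value, b.value.shape))

    return Tensor(out_val, _parents=(a, b), _backward=bwd)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.value > 0
    out_val = np.where(mask, x.value, 0.0)

    def bwd(g):
        _accum(x, g * mask)

    return Tensor(out_val, _parents=(x,), _backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_val = 1.0 / (1.0 + np.exp(-np.clip(x.value, -60.0, 60.0)))

    def bwd(g):
        _accum(x, g * out_val * (1.0 - out_val))

    return Tensor(out_val, _parents=(x,), _backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(out_val, _parents=tuple(tensors), _backward=bwd)


def segment_sum(x: Tensor, offsets: np.ndarray) -> Tensor:
    """Sum rows of ``x`` within contiguous segments.

    ``offsets`` are segment start indices (length = number of segments,
    offsets[0] == 0); segment i spans rows offsets[i]:offsets[i+1].
    """
    x = _as_tensor(x)
    offsets = np.asarray(offsets, dtype=np.intp)
    counts = np.diff(np.append(offsets, x.value.shape[0]))
    out_val = np.add.reduceat(x.value, offsets, axis=0)

    def bwd(g):
        _accum(x, np.repeat(g, counts, axis=0))

    return Tensor(out_val, _parents=(x,), _backward=bwd)


def segment_max(x: Tensor, offsets: np.ndarray) -> Tensor:
    """Elementwise max of rows within contiguous segments (ties -> first row)."""
    x = _as_tensor(x)
    offsets = np.asarray(offsets, dtype=np.intp)
    n_rows, n_cols = x.value.shape
    bounds = np.append(offsets, n_rows)
    out_val = np.maximum.reduceat(x.value, offsets, axis=0)
    # first-occurrence argmax per segment, for gradient routing
    argmax = np.empty((len(offsets), n_cols), dtype=np.intp)
    for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        argmax[i] = lo + np.argmax(x.value[lo:hi], axis=0)

    def bwd(g):
        gx = np.zeros_like(x.value)
        cols = np.arange(n_cols)
        for i in range(len(offsets)):
            gx[argmax[i], cols] += g[i]
        _accum(x, gx)

    return Tensor(out_val, _parents=(x,), _backward=bwd)


def total_sum(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_val = np.asarray(x.value.sum())

    def bwd(g):
        _accum(x, np.broadcast_to(g, x.value.shape).copy())

    return Tensor(out_val, _parents=(x,), _backward=bwd)


def mean_square(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error between a prediction tensor and a constant target."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64).reshape(pred.value.shape)
    diff = pred.value - target
    n = diff.size
    out_val = np.asarray((diff**2).mean())

    def bwd(g):
        _accum(pred, (2.0 / n) * diff * g)

    return Tensor(out_val, _parents=(pred,), _backward=bwd)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    logits = _as_tensor(logits)
    z = logits.value
    y = np.asarray(target, dtype=np.float64).reshape(z.shape)
    n = z.size
    # softplus(z) - z*y, computed stably
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_val = np.asarray(loss.mean())
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))

    def bwd(g):
        _accum(logits, (p - y) / n * g)

    return Tensor(out_val, _parents=(logits,), _backward=bwd)
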