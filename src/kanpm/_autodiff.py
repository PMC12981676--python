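"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine implements exactly the operations the encoders, fusion blocks and
KAN head need: broadcast arithmetic, (batched) matmul, the usual pointwise
nonlinearities, reductions, reshaping, fancy indexing with scatter-add
backward, and segment operations for graph message passing.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` in reverse
topological order.

Design notes
------------
* An op only records the graph when at least one input requires gradients;
  pure inference therefore allocates no tape.
* dtype is preserved: model parameters are float32 for speed, while analysis
  helpers (e.g. raw B-spline evaluation) can stay in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "segment_sum",
    "segment_softmax",
    "softmax_lastaxis",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # ---- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        _accum(self, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # ---- fluent helpers ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


# ---------------------------------------------------------------------------
# plumbing
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _coerce_pair(a, b):
    """Wrap plain numbers/arrays as Tensors, matching the partner's dtype so
    Python-float constants never upcast a float32 graph to float64."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and not isinstance(a, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return _as_tensor(a), _as_tensor(b)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g), t.data.shape)
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype)
    else:
        t.grad += g


def _make(out_data, parents, backward_fn) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=req)
    if req:
        out._prev = tuple(parents)
        out._backward = backward_fn
    return out


# ---------------------------------------------------------------------------
# elementwise / arithmetic ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _coerce_pair(a, b)

    def back(g):
        _accum(a, g)
        _accum(b, g)

    return _make(a.data + b.data, (a, b), back)


def sub(a, b):
    a, b = _coerce_pair(a, b)

    def back(g):
        _accum(a, g)
        _accum(b, -g)

    return _make(a.data - b.data, (a, b), back)


def mul(a, b):
    a, b = _coerce_pair(a, b)

    def back(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(a.data * b.data, (a, b), back)


def div(a, b):
    a, b = _coerce_pair(a, b)
    out_data = a.data / b.data

    def back(g):
        _accum(a, g / b.data)
        _accum(b, -g * out_data / b.data)

    return _make(out_data, (a, b), back)


def power(a, p: float):
    a = _as_tensor(a)
    out_data = a.data ** p

    def back(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), back)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def back(g):
        _accum(a, np.matmul(g, np.swapaxes(b.data, -1, -2)))
        _accum(b, np.matmul(np.swapaxes(a.data, -1, -2), g))

    return _make(np.matmul(a.data, b.data), (a, b), back)


def texp(a):
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def back(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), back)


def tlog(a):
    a = _as_tensor(a)

    def back(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), back)


def tsqrt(a):
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def back(g):
        _accum(a, g * 0.5 / out_data)

    return _make(out_data, (a,), back)


def tanh(a):
    a = _as_tensor(a)
    out_data = np.tanh(a.data)

    def back(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), back)


def sigmoid(a):
    a = _as_tensor(a)
    with np.errstate(over="ignore"):
        out_data = 1.0 / (1.0 + np.exp(-a.data))

    def back(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), back)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0

    def back(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), back)


def leaky_relu(a, slope: float = 0.2):
    a = _as_tensor(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope).astype(a.data.dtype)

    def back(g):
        _accum(a, g * scale)

    return _make(a.data * scale, (a,), back)


def silu(a):
    """x * sigmoid(x) (a.k.a. swish)."""
    a = _as_tensor(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def back(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _make(out_data, (a,), back)


def clip(a, lo: float, hi: float):
    """Clamp; gradient is zero outside [lo, hi] (straight-through inside)."""
    a = _as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def back(g):
        _accum(a, g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), back)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape))

    return _make(out_data, (a,), back)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = _as_tensor(a)
    orig = a.data.shape

    def back(g):
        _accum(a, np.asarray(g).reshape(orig))

    return _make(a.data.reshape(shape), (a,), back)


def transpose(a, axes):
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def back(g):
        _accum(a, np.transpose(np.asarray(g), inv))

    return _make(np.transpose(a.data, axes), (a,), back)


def getitem(a, idx):
    a = _as_tensor(a)

    def back(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        _accum(a, buf)

    return _make(a.data[idx], (a,), back)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back)


def stack(tensors, axis=0):
    expanded = []
    for t in tensors:
        t = _as_tensor(t)
        shape = list(t.data.shape)
        shape.insert(axis, 1)
        expanded.append(reshape(t, tuple(shape)))
    return concat(expanded, axis=axis)


# ---------------------------------------------------------------------------
# segment ops (graph message passing) and softmax helpers
# ---------------------------------------------------------------------------

def segment_sum(a, seg_ids: np.ndarray, num_segments: int):
    """Sum rows of ``a`` into ``num_segments`` buckets given per-row ids."""
    a = _as_tensor(a)
    out_shape = (num_segments,) + a.data.shape[1:]
    out_data = np.zeros(out_shape, dtype=a.data.dtype)
    np.add.at(out_data, seg_ids, a.data)

    def back(g):
        _accum(a, np.asarray(g)[seg_ids])

    return _make(out_data, (a,), back)


def segment_softmax(scores, seg_ids: np.ndarray, num_segments: int):
    """Softmax of a 1-D score vector within each segment.

    Fused primitive (single graph node): numerically shifted by the
    per-segment maximum; backward uses the standard softmax Jacobian
    restricted to each segment.
    """
    scores = _as_tensor(scores)
    seg_max = np.full(num_segments, -np.inf, dtype=scores.data.dtype)
    np.maximum.at(seg_max, seg_ids, scores.data)
    e = np.exp(scores.data - seg_max[seg_ids])
    denom = np.zeros(num_segments, dtype=e.dtype)
    np.add.at(denom, seg_ids, e)
    out_data = e / denom[seg_ids]

    def back(g):
        dot = np.zeros(num_segments, dtype=e.dtype)
        np.add.at(dot, seg_ids, np.asarray(g) * out_data)
        _accum(scores, out_data * (np.asarray(g) - dot[seg_ids]))

    return _make(out_data, (scores,), back)


def softmax_lastaxis(a, additive_mask=None):
    """Softmax over the last axis; ``additive_mask`` is a constant array added
    to the logits (use large negative values to mask positions).

    Fused primitive: one graph node for the whole shift/exp/normalize chain.
    """
    a = _as_tensor(a)
    logits = a.data if additive_mask is None else a.data + additive_mask
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def back(g):
        g = np.asarray(g)
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), back)


def dropout(a, p: float, rng: np.random.Generator, training: bool):
    if not training or p <= 0.0:
        return _as_tensor(a)
    a = _as_tensor(a)
    keep = (rng.random(a.data.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    return mul(a, Tensor(keep))
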