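"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for a 3D residual encoder-decoder: tensors wrap
ndarrays and record a backward closure; ``backward()`` runs the tape in
reverse topological order. Convolutions are built on
``numpy.lib.stride_tricks.sliding_window_view`` + ``einsum`` so no im2col
copies are materialized. Only the ops the network and losses need are
implemented; everything is float64 and single-threaded.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "add", "mul", "neg", "const_mul", "log", "square", "sum_",
    "mean", "concat", "sigmoid", "leaky_relu", "conv3d", "conv1x1",
    "maxpool3d", "conv_transpose3d", "global_avg_pool",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep at toy scale already
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def _unbroadcast(g, shape):
    """Sum gradient g down to the given (broadcast-source) shape."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _op(data, parents, backward):
    return Tensor(data, parents=parents, backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _op(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _op(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    return const_mul(a, -1.0)


def const_mul(a: Tensor, c) -> Tensor:
    c = np.asarray(c, dtype=np.float64)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * c, a.shape))

    return _op(a.data * c, (a,), backward)


def log(a: Tensor, eps: float = 1e-12) -> Tensor:
    clipped = np.maximum(a.data, eps)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / clipped * (a.data >= eps))

    return _op(np.log(clipped), (a,), backward)


def square(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(2.0 * g * a.data)

    return _op(a.data**2, (a,), backward)


def sum_(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full(a.shape, float(g)))

    return _op(a.data.sum(), (a,), backward)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full(a.shape, float(g) / n))

    return _op(a.data.mean(), (a,), backward)


def concat(tensors, axis=1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accumulate(g[tuple(sl)])
            start += s

    return _op(out_data, tuple(tensors), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _op(s, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.1) -> Tensor:
    factor = np.where(a.data > 0, 1.0, slope)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * factor)

    return _op(a.data * factor, (a,), backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3x3x3 same-padding stride-1 convolution.

    x: (N, C, D, H, W); w: (O, C, 3, 3, 3); b: (O,) or None.
    """
    k = w.shape[-1]
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    out_data = np.einsum("ncdhwijk,ocijk->nodhw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("ncdhwijk,nodhw->ocijk", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
            gwin = sliding_window_view(gp, (k, k, k), axis=(2, 3, 4))
            wflip = w.data[:, :, ::-1, ::-1, ::-1]
            x._accumulate(
                np.einsum("nodhwijk,ocijk->ncdhw", gwin, wflip, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _op(out_data, parents, backward)


def conv1x1(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Pointwise (1x1x1) convolution; w: (O, C)."""
    out_data = np.einsum("ncdhw,oc->nodhw", x.data, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("ncdhw,nodhw->oc", x.data, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            x._accumulate(np.einsum("nodhw,oc->ncdhw", g, w.data, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _op(out_data, parents, backward)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2."""
    n, c, d, h, w = x.shape
    r = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    r2 = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
    arg = r2.argmax(axis=-1)
    out_data = np.take_along_axis(r2, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gr = np.zeros_like(r2)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
            gx = gr.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            gx = gx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(x.shape)
            x._accumulate(gx)

    return _op(out_data, (x,), backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2x2 transposed convolution with stride 2 (non-overlapping upsampling).

    x: (N, C, D, H, W); w: (C, O, 2, 2, 2) -> output (N, O, 2D, 2H, 2W).
    """
    n, c, d, h, wd = x.shape
    o = w.shape[1]
    y = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data, optimize=True)
    out_data = y.reshape(n, o, 2 * d, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]

    def backward(g):
        gr = g.reshape(n, o, d, 2, h, 2, wd, 2)
        if w.requires_grad:
            w._accumulate(np.einsum("ncdhw,nodihjwk->coijk", x.data, gr, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            x._accumulate(np.einsum("nodihjwk,coijk->ncdhw", gr, w.data, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _op(out_data, parents, backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes, keepdims: (N, C, 1, 1, 1)."""
    nvox = int(np.prod(x.shape[2:]))
    out_data = x.data.mean(axis=(2, 3, 4), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / nvox, x.shape).copy())

    return _op(out_data, (x,), backward)
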