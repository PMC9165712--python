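"""Minimal reverse-mode autodiff on NCHW numpy arrays.

The segmentation networks in this package are built from a handful of
operations — 3x3/1x1 convolutions, 2x2 stride-2 transposed convolutions,
2x2 max-pooling, batch normalization, ReLU/sigmoid, channel concatenation
and elementwise addition — so the engine implements exactly those, each
with a hand-derived backward pass.  Convolutions are evaluated as im2col
matrix products (BLAS-bound); the column matrices are recomputed during
the backward pass rather than cached, trading a little compute for a much
smaller peak memory footprint.

Gradient correctness is established by finite-difference checks in the
test suite; everything above this module (blocks, networks, training)
relies on it.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "grad_enabled",
    "add",
    "concat_channels",
    "relu",
    "sigmoid",
    "conv2d",
    "conv_transpose2d_2x2",
    "maxpool2x2",
    "upsample_nearest2x",
]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """An ndarray plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents) if grad_enabled() else ()
        self._backward = backward if grad_enabled() else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Reverse-topological accumulation of gradients from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can be hundreds of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        # leaves always participate in the graph, even when created under no_grad
        self.requires_grad = True


def _track(*tensors: Tensor) -> bool:
    return grad_enabled() and any(t.requires_grad or t._parents for t in tensors)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    if not _track(a, b):
        return Tensor(out)
    return Tensor(out, parents=(a, b), backward=lambda g: (g, g))


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=1)
    if not _track(*tensors):
        return Tensor(out)
    sizes = [t.data.shape[1] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=1))

    return Tensor(out, parents=tensors, backward=backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    if not _track(x):
        return Tensor(out)
    mask = x.data > 0
    return Tensor(out, parents=(x,), backward=lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable piecewise form: never exponentiates a positive value
    d = x.data
    out = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))), np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    if not _track(x):
        return Tensor(out)
    return Tensor(out, parents=(x,), backward=lambda g: (g * out * (1.0 - out),))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) columns for a stride-1 'same' convolution."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h * w), dtype=x.dtype)
    for ky in range(k):
        for kx in range(k):
            cols[:, :, ky, kx, :] = xp[:, :, ky : ky + h, kx : kx + w].reshape(n, c, h * w)
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter column gradients back onto the padded image."""
    n, c, h, w = shape
    pad = k // 2
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h * w)
    for ky in range(k):
        for kx in range(k):
            dxp[:, :, ky : ky + h, kx : kx + w] += dcols[:, :, ky, kx, :].reshape(n, c, h, w)
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1, 'same'-padded convolution; weight is (F, C, k, k) with k odd."""
    f, c, k, k2 = weight.data.shape
    if k != k2 or k % 2 == 0:
        raise ValueError("conv2d expects square odd kernels")
    n, cin, h, w = x.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input has {cin}, weight expects {c}")
    wm = weight.data.reshape(f, c * k * k)
    if k == 1:
        out = np.matmul(wm, x.data.reshape(n, c, h * w))
    else:
        out = np.matmul(wm, _im2col(x.data, k))
    out = out.reshape(n, f, h, w)
    if bias is not None:
        out += bias.data.reshape(1, f, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if not _track(*parents):
        return Tensor(out)

    def backward(g):
        gm = g.reshape(n, f, h * w)
        if k == 1:
            cols = x.data.reshape(n, c, h * w)
        else:
            cols = _im2col(x.data, k)  # recomputed: cheaper than caching per layer
        dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(f, c, k, k)
        dcols = np.matmul(wm.T, gm)
        if k == 1:
            dx = dcols.reshape(n, c, h, w)
        else:
            dx = _col2im(dcols, x.data.shape, k)
        if bias is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    return Tensor(out, parents=parents, backward=backward)


def conv_transpose2d_2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2x2, stride-2 transposed convolution (the classic up-convolution).

    weight is (Cin, Cout, 2, 2); output spatial size is exactly doubled.
    """
    cin, cout, kh, kw = weight.data.shape
    if (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2d_2x2 expects a 2x2 kernel")
    n, c, h, w = x.data.shape
    if c != cin:
        raise ValueError(f"transposed-conv channel mismatch: input {c}, weight {cin}")
    xm = x.data.reshape(n, cin, h * w)
    out = np.empty((n, cout, 2 * h, 2 * w), dtype=x.data.dtype)
    for i in range(2):
        for j in range(2):
            y = np.matmul(weight.data[:, :, i, j].T, xm)  # (N, Cout, H*W)
            out[:, :, i::2, j::2] = y.reshape(n, cout, h, w)
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if not _track(*parents):
        return Tensor(out)

    def backward(g):
        dx = np.zeros_like(x.data).reshape(n, cin, h * w)
        dw = np.zeros_like(weight.data)
        for i in range(2):
            for j in range(2):
                gij = g[:, :, i::2, j::2].reshape(n, cout, h * w)
                dx += np.matmul(weight.data[:, :, i, j], gij)
                dw[:, :, i, j] = np.matmul(xm, gij.transpose(0, 2, 1)).sum(axis=0)
        dx = dx.reshape(n, cin, h, w)
        if bias is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    return Tensor(out, parents=parents, backward=backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Parameter-free 2x nearest-neighbour upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    if not _track(x):
        return Tensor(out)
    n, c, h, w = x.data.shape

    def backward(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor(out, parents=(x,), backward=backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    windows = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    if not _track(x):
        return Tensor(out)

    def backward(g):
        dwin = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        return (dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w),)

    return Tensor(out, parents=(x,), backward=backward)
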