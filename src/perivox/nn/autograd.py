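"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute core of the segmentation network: a small define-by-run
graph of :class:`Tensor` nodes supporting exactly the operations the nested
encoder--decoder needs (im2col convolution, 2x2 max pooling, bilinear 2x
upsampling, batch normalisation, channel concatenation, elementwise
arithmetic and reductions).  Everything runs in float32; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "div",
    "concat",
    "relu",
    "sigmoid",
    "tsum",
    "tmean",
    "conv2d",
    "maxpool2x2",
    "upsample_bilinear2x",
    "batchnorm2d",
]

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return Tensor._result(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.data.shape)),
            (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)),
        )

    return Tensor._result(out_data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0).astype(_F32)

    def backward(g):
        return ((a, g * mask),)

    return Tensor._result(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    out_data = out_data.astype(_F32)

    def backward(g):
        return ((a, g * out_data * (1.0 - out_data)),)

    return Tensor._result(out_data, (a,), backward)


# -- reductions -----------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims, dtype=_F32)

    def backward(g):
        g = np.asarray(g, dtype=_F32)
        if axis is None:
            return ((a, np.broadcast_to(g, a.data.shape).astype(_F32)),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            for ax in sorted(ax % a.data.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        return ((a, np.broadcast_to(g, a.data.shape).astype(_F32)),)

    return Tensor._result(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor._result(out_data, tuple(tensors), backward)


# -- convolution ----------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int):
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix, stride 1, 'same' output."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=_F32)
    dcols = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, k: int, pad: int) -> Tensor:
    """Stride-1 'same' convolution; ``weight`` has shape (cout, cin*k*k)."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    cols = _im2col(x.data, k, pad)  # (N*H*W, C*k*k)
    out = cols @ weight.data.T  # (N*H*W, cout)
    cout = weight.data.shape[0]
    out = out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    out = np.ascontiguousarray(out, dtype=_F32)
    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gr = g.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        grads = []
        if x.requires_grad:
            dcols = gr @ weight.data  # (N*H*W, C*k*k)
            grads.append((x, _col2im(dcols, x.data.shape, k, pad)))
        if weight.requires_grad:
            grads.append((weight, (gr.T @ cols).astype(_F32)))
        if bias is not None and bias.requires_grad:
            grads.append((bias, gr.sum(axis=0).astype(_F32)))
        return tuple(grads)

    return Tensor._result(out, parents, backward)


# -- pooling / resampling -------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    x = _wrap(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial sides, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = blocks.max(axis=(3, 5))
    # distribute gradient equally over tied maxima (deterministic)
    mask = (blocks == out[:, :, :, None, :, None]).astype(_F32)
    mask /= mask.sum(axis=(3, 5), keepdims=True)

    def backward(g):
        gb = mask * g[:, :, :, None, :, None]
        return ((x, gb.reshape(n, c, h, w)),)

    return Tensor._result(np.ascontiguousarray(out), (x,), backward)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic linear-interpolation matrix, half-pixel-centre convention."""
    key = (n_out, n_in)
    m = _INTERP_CACHE.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=_F32)
        scale = n_in / n_out
        for i in range(n_out):
            src = (i + 0.5) * scale - 0.5
            lo = int(np.floor(src))
            t = src - lo
            lo_c = min(max(lo, 0), n_in - 1)
            hi_c = min(max(lo + 1, 0), n_in - 1)
            m[i, lo_c] += 1.0 - t
            m[i, hi_c] += t
        _INTERP_CACHE[key] = m
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    x = _wrap(x)
    n, c, h, w = x.data.shape
    mh = _interp_matrix(2 * h, h)
    mw = _interp_matrix(2 * w, w)
    out = np.einsum("oh,nchw,pw->ncop", mh, x.data, mw, optimize=True).astype(_F32)

    def backward(g):
        dx = np.einsum("oh,ncop,pw->nchw", mh, g, mw, optimize=True).astype(_F32)
        return ((x, dx),)

    return Tensor._result(out, (x,), backward)


# -- batch normalisation ---------------------------------------------------

def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel normalisation over (N, H, W); updates running stats in place."""
    x = _wrap(x)
    c = x.data.shape[1]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(_F32)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        grads = []
        if gamma.requires_grad:
            grads.append((gamma, (g * xhat).sum(axis=(0, 2, 3)).astype(_F32)))
        if beta.requires_grad:
            grads.append((beta, g.sum(axis=(0, 2, 3)).astype(_F32)))
        if x.requires_grad:
            gs = gamma.data.reshape(1, c, 1, 1)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gxhat = g * gs
                dx = (
                    gxhat
                    - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                ) * inv_std.reshape(1, c, 1, 1)
            else:
                dx = g * gs * inv_std.reshape(1, c, 1, 1)
            grads.append((x, dx.astype(_F32)))
        return tuple(grads)

    return Tensor._result(out.astype(_F32), (x, gamma, beta), backward)
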