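"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order.  Only the primitives the segmentation network needs are provided —
broadcast arithmetic, matmul, 2-D convolution (grouped/depthwise), pooling,
indexing/reshaping, and the usual pointwise nonlinearities.  Everything is
dtype-agnostic so tests can run gradient checks in float64 while the model
trains in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "no_grad", "is_grad_enabled",
    "add", "sub", "mul", "div", "neg", "pow_", "exp", "log", "sqrt",
    "sigmoid", "relu", "softplus", "silu", "tanh",
    "matmul", "conv2d", "avg_pool2d", "global_max_pool2d",
    "reshape", "transpose", "flip", "concat", "pad2d", "index_select", "narrow",
    "sum_", "mean_", "clamp", "softmax",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
            if data.dtype.kind != "f":
                data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self._backward = None
        self._parents = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autograd -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other, self.dtype))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _wrap(other, self.dtype))

    def __rsub__(self, other):
        return sub(_wrap(other, self.dtype), self)

    def __mul__(self, other):
        return mul(self, _wrap(other, self.dtype))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other, self.dtype))

    def __rtruediv__(self, other):
        return div(_wrap(other, self.dtype), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other, self.dtype))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)


def _wrap(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if is_grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g, owned: bool = False):
    """Accumulate gradient ``g`` into ``t``.  ``owned=True`` promises the
    caller hands over a freshly allocated array that no one else aliases,
    letting us skip the defensive copy."""
    if not t.requires_grad:
        return
    if t.grad is None:
        if owned and isinstance(g, np.ndarray) and g.dtype == t.data.dtype \
                and g.flags.writeable:
            t.grad = g
        else:
            t.grad = np.asarray(g, dtype=t.data.dtype).copy()
    else:
        t.grad += g


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))
    return _make(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(-g, b.shape), owned=b.shape == g.shape)
    return _make(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape), owned=a.shape == g.shape)
        _accum(b, _unbroadcast(g * a.data, b.shape), owned=b.shape == g.shape)
    return _make(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.shape), owned=a.shape == g.shape)
        _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape), owned=b.shape == g.shape)
    return _make(a.data / b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, -g, owned=True)
    return _make(-a.data, (a,), backward)


def pow_(a: Tensor, p: float) -> Tensor:
    def backward(g):
        _accum(a, g * p * a.data ** (p - 1), owned=True)
    return _make(a.data ** p, (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data, owned=True)
    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g / a.data, owned=True)
    return _make(np.log(a.data), (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def backward(g):
        _accum(a, g * 0.5 / out_data, owned=True)
    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable logistic
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(x.dtype)

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data), owned=True)
    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask, owned=True)
    return _make(a.data * mask, (a,), backward)


def softplus(a: Tensor) -> Tensor:
    x = a.data
    out_data = (np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))).astype(x.dtype)

    def backward(g):
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        _accum(a, g * s, owned=True)
    return _make(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data ** 2), owned=True)
    return _make(out_data, (a,), backward)


def silu(a: Tensor) -> Tensor:
    return mul(a, sigmoid(a))


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        _accum(a, g * mask, owned=True)
    return _make(np.clip(a.data, lo, hi), (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.shape))
    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g / n, a.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g / n, a.shape))
    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])

    def backward(g):
        _accum(a, g.reshape(a.shape))
    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))
    return _make(a.data.transpose(axes), (a,), backward)


def flip(a: Tensor, axis: int) -> Tensor:
    def backward(g):
        _accum(a, np.flip(g, axis=axis))
    return _make(np.flip(a.data, axis=axis).copy(), (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice [start, start+length) along ``axis``."""
    sl = (slice(None),) * axis + (slice(start, start + length),)

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[sl] = g
        _accum(a, ga)
    return _make(a.data[sl].copy(), (a,), backward)


def index_select(a: Tensor, idx, axis: int) -> Tensor:
    """Gather along ``axis`` with integer indices (a permutation or subset)."""
    idx = np.asarray(idx)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, (slice(None),) * axis + (idx,), g)
        _accum(a, ga)
    return _make(np.take(a.data, idx, axis=axis), (a,), backward)


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the last two axes symmetrically."""
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]

    def backward(g):
        sl = (slice(None),) * (a.ndim - 2) + (slice(pad, -pad), slice(pad, -pad))
        _accum(a, g[sl])
    return _make(np.pad(a.data, width), (a,), backward)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            bt = np.swapaxes(b.data, -1, -2)
            ga = g @ bt
            _accum(a, _unbroadcast_matmul(ga, a.shape))
        if b.requires_grad:
            at = np.swapaxes(a.data, -1, -2)
            gb = at @ g
            _accum(b, _unbroadcast_matmul(gb, b.shape))
    return _make(a.data @ b.data, (a, b), backward)


def _unbroadcast_matmul(g, shape):
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i in range(g.ndim - 2) if shape[i] == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max for stability; softmax is shift-invariant
    shifted = sub(a, Tensor(a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return div(e, sum_(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# convolution & pooling
# ---------------------------------------------------------------------------

def _im2col(xp, Ho, Wo, kh, kw, stride):
    """Column matrix (N, C·kh·kw, Ho·Wo) built from contiguous slices."""
    N, C, _, _ = xp.shape
    cols = np.empty((N, C, kh * kw, Ho * Wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j, :] = \
                xp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride].reshape(N, C, -1)
    return cols.reshape(N, C * kh * kw, Ho * Wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation on NCHW input.

    ``w`` has shape (C_out, C_in/groups, kh, kw).  Three execution paths:
    a plain GEMM for pointwise convs, numba loops for depthwise convs
    (``groups == C_in == C_out``), and im2col + GEMM for everything else.
    """
    from ._conv_kernels import dw_conv_bwd, dw_conv_fwd

    N, C, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    if C % groups or Cout % groups or Cin_g != C // groups:
        raise ValueError(f"channel/group mismatch: x has {C} channels, "
                         f"w is {w.shape} with groups={groups}")
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("empty output; input smaller than kernel")

    pointwise = kh == kw == 1 and stride == 1 and groups == 1
    depthwise = groups == C and Cout == C and not pointwise

    if pointwise:
        cols = x.data.reshape(N, C, H * W)
        out = np.matmul(w.data.reshape(Cout, C), cols).reshape(N, Cout, Ho, Wo)
    elif depthwise:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x.data
        xp = np.ascontiguousarray(xp)
        out = np.empty((N, C, Ho, Wo), dtype=x.data.dtype)
        dw_conv_fwd(xp, w.data.reshape(C, kh, kw), out, stride)
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x.data
        if groups == 1:
            cols = _im2col(xp, Ho, Wo, kh, kw, stride)
            out = np.matmul(w.data.reshape(Cout, C * kh * kw), cols) \
                .reshape(N, Cout, Ho, Wo)
        else:
            cols = _im2col(xp, Ho, Wo, kh, kw, stride) \
                .reshape(N, groups, Cin_g * kh * kw, Ho * Wo)
            wg = w.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
            out = np.matmul(wg, cols).reshape(N, Cout, Ho, Wo)

    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        gL = g.reshape(N, Cout, Ho * Wo)
        if pointwise:
            if w.requires_grad:
                gw = np.einsum("noL,niL->oi", gL, x.data.reshape(N, C, H * W),
                               optimize=True)
                _accum(w, gw.reshape(w.shape))
            if x.requires_grad:
                gx = np.matmul(w.data.reshape(Cout, C).T, gL).reshape(N, C, H, W)
                _accum(x, gx)
            return
        Hp, Wp = H + 2 * padding, W + 2 * padding
        xp2 = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                              (padding, padding))) if padding else x.data
        if depthwise:
            xp2 = np.ascontiguousarray(xp2)
            gxp = np.zeros((N, C, Hp, Wp), dtype=x.data.dtype)
            gw = np.zeros((C, kh, kw), dtype=w.data.dtype)
            dw_conv_bwd(xp2, w.data.reshape(C, kh, kw), g, gxp, gw, stride)
            if w.requires_grad:
                _accum(w, gw.reshape(w.shape))
            if x.requires_grad:
                gx = gxp[:, :, padding:Hp - padding, padding:Wp - padding] \
                    if padding else gxp
                _accum(x, gx)
            return
        cols2 = _im2col(xp2, Ho, Wo, kh, kw, stride)
        if groups == 1:
            if w.requires_grad:
                gw = np.einsum("noL,nkL->ok", gL, cols2, optimize=True)
                _accum(w, gw.reshape(w.shape))
            if x.requires_grad:
                gcols = np.matmul(w.data.reshape(Cout, C * kh * kw).T, gL)
                gx = _col2im(gcols.reshape(N, C, kh * kw, Ho, Wo),
                             (N, C, Hp, Wp), kh, kw, stride)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                _accum(x, gx)
        else:
            colsg = cols2.reshape(N, groups, Cin_g * kh * kw, Ho * Wo)
            gLg = gL.reshape(N, groups, Cout // groups, Ho * Wo)
            wg = w.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
            if w.requires_grad:
                gw = np.einsum("ngoL,ngkL->gok", gLg, colsg, optimize=True)
                _accum(w, gw.reshape(w.shape))
            if x.requires_grad:
                gcols = np.einsum("gko,ngoL->ngkL", wg.transpose(0, 2, 1), gLg,
                                  optimize=True)
                gx = _col2im(gcols.reshape(N, C, kh * kw, Ho, Wo),
                             (N, C, Hp, Wp), kh, kw, stride)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                _accum(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def _col2im(gcols, padded_shape, kh, kw, stride):
    """Scatter window gradients (N,C,kh·kw,Ho,Wo) back onto the padded image."""
    N, C, Hp, Wp = padded_shape
    _, _, _, Ho, Wo = gcols.shape
    gx = np.zeros(padded_shape, dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                gcols[:, :, i * kw + j, :, :]
    return gx


def avg_pool2d(x: Tensor, k: int = 3, stride: int = 1, padding: int = 1) -> Tensor:
    """Mean pooling with zero padding (size-preserving at k=3,s=1,p=1)."""
    N, C, H, W = x.shape
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    sN, sC, sH, sW = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(N, C, Ho, Wo, k, k),
        strides=(sN, sC, sH * stride, sW * stride, sH, sW), writeable=False)
    out = windows.mean(axis=(4, 5))

    def backward(g):
        gcols = np.broadcast_to((g / (k * k))[:, :, None, :, :], (N, C, k * k, Ho, Wo))
        gx = _col2im(np.ascontiguousarray(gcols),
                     (N, C, H + 2 * padding, W + 2 * padding), k, k, stride)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        _accum(x, gx)
    return _make(out, (x,), backward)


def global_max_pool2d(x: Tensor) -> Tensor:
    """Adaptive max pooling to a 1x1 spatial footprint: (N,C,H,W) -> (N,C,1,1)."""
    N, C, H, W = x.shape
    flat = x.data.reshape(N, C, H * W)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[..., None], axis=2).reshape(N, C, 1, 1)

    def backward(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[..., None], g.reshape(N, C, 1), axis=2)
        _accum(x, gx.reshape(x.shape))
    return _make(out, (x,), backward)


def norm_affine(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
                eps: float, mean=None, var=None):
    """Fused (x − mean)/sqrt(var + eps) · gamma + beta.

    ``axes`` are the reduction axes of mean/var; ``gamma``/``beta`` must be
    pre-shaped to broadcast against x.  Pass precomputed ``mean``/``var``
    (plain arrays broadcastable to x) to normalise with external statistics
    (e.g. running statistics in eval mode).  Returns (out, mean, var).
    """
    xd = x.data
    if mean is None:
        mean = xd.mean(axis=axes, keepdims=True)
        var = ((xd - mean) ** 2).mean(axis=axes, keepdims=True)
        stats_from_batch = True
    else:
        stats_from_batch = False
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=xd.dtype))
    xhat = (xd - mean) * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            red = tuple(i for i in range(g.ndim) if gamma.data.shape[i] == 1)
            _accum(gamma, (g * xhat).sum(axis=red, keepdims=True), owned=True)
        if beta.requires_grad:
            red = tuple(i for i in range(g.ndim) if beta.data.shape[i] == 1)
            _accum(beta, g.sum(axis=red, keepdims=True), owned=True)
        if x.requires_grad:
            dxhat = g * gamma.data
            if stats_from_batch:
                m1 = dxhat.mean(axis=axes, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
                gx = inv * (dxhat - m1 - xhat * m2)
            else:
                gx = inv * dxhat
            _accum(x, gx.astype(xd.dtype, copy=False), owned=True)

    return _make(out, (x, gamma, beta), backward), mean, var
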