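"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape: every operation returns a :class:`Tensor` that
remembers its parents and a closure computing vector-Jacobian products.
Feature maps follow the channels-last convention ``(batch, height, width,
channels)`` throughout; all arithmetic is float32.

Only the operations the nuclei networks need are implemented: broadcasted
elementwise arithmetic, reductions, dense/convolutional/transposed/depthwise
linear maps, 2x2 pooling and upsampling, batch normalisation, softmax and the
fused softmax cross-entropy.
"""
from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / metric evaluation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """Array node in the autograd graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- convenience ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return mul(self, _as_tensor(np.float32(-1.0)))

    # -- backprop ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (unrolled recurrences)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the tape
        for node in topo:
            node._backward = None
            node._parents = ()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    else:
        out.requires_grad = False
        out._parents = ()
        out._backward = None
    return out


def _accum(t: Tensor, g: np.ndarray, own: bool = False) -> None:
    """Accumulate a vector-Jacobian product into ``t.grad``.

    ``own=True`` promises that ``g`` is a freshly allocated array no other
    node can alias, so it may be adopted without copying.
    """
    if not t.requires_grad:
        return
    g = g.astype(np.float32, copy=False)
    if t.grad is None:
        t.grad = g if own else np.array(g, dtype=np.float32)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape), own=True)
        _accum(b, _unbroadcast(g * a.data, b.data.shape), own=True)

    return _make(out, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape), own=True)
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape), own=True)

    return _make(out, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)

    def backward(g):
        _accum(x, g * (x.data > 0), own=True)

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -80.0, 80.0)))

    def backward(g):
        _accum(x, g * out * (1.0 - out), own=True)

    return _make(out, (x,), backward)


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

    def backward(g):
        if axis is None:
            _accum(x, np.broadcast_to(g, x.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(x, np.broadcast_to(g, x.data.shape))

    return _make(np.asarray(out, dtype=np.float32), (x,), backward)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in np.atleast_1d(axis)])
    return mul(tsum(x, axis=axis, keepdims=keepdims),
               _as_tensor(np.float32(1.0 / n)))


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = list(tensors)
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(out, ts, backward)


# -- dense / convolutional maps -------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        _accum(x, g @ w.data.T, own=True)
        _accum(w, x.data.T @ g, own=True)
        if b is not None:
            _accum(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 cross-correlation; w has shape (kh, kw, cin, cout).

    Computed by kernel-tap decomposition: for each of the kh*kw taps one GEMM
    runs over the full (contiguous) padded array and the product is
    accumulated through a shifted view.  This avoids materialising an im2col
    matrix, whose assembly is strided-copy bound on wide feature maps.
    """
    kh, kw, cin, cout = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes")
    if x.data.shape[-1] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[-1]}, kernel expects {cin}")
    ph, pw = kh // 2, kw // 2
    n, h, wd, _ = x.data.shape
    hp, wp = h + 2 * ph, wd + 2 * pw
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0))) if ph or pw else x.data
    xf = xp.reshape(n * hp * wp, cin)
    taps = [(i, j) for i in range(kh) for j in range(kw)]
    # narrow layers (e.g. growth-rate-12 dense layers) run one wide GEMM over
    # all taps at once; wide layers loop taps to bound the temporary size
    narrow = kh * kw * cout <= 512

    if narrow:
        wcat = np.ascontiguousarray(
            w.data.reshape(kh * kw, cin, cout).transpose(1, 0, 2)
        ).reshape(cin, kh * kw * cout)
        pv = (xf @ wcat).reshape(n, hp, wp, kh * kw, cout)
        out = np.zeros((n, h, wd, cout), dtype=np.float32)
        for k, (i, j) in enumerate(taps):
            out += pv[:, i:i + h, j:j + wd, k, :]
    else:
        out = np.zeros((n, h, wd, cout), dtype=np.float32)
        for i, j in taps:
            prod = (xf @ w.data[i, j]).reshape(n, hp, wp, cout)
            out += prod[:, i:i + h, j:j + wd, :]
    if b is not None:
        out += b.data

    def backward(g):
        if narrow and (w.requires_grad or x.requires_grad):
            zcat = np.zeros((n, hp, wp, kh * kw, cout), dtype=np.float32)
            for k, (i, j) in enumerate(taps):
                zcat[:, i:i + h, j:j + wd, k, :] = g
            zf = zcat.reshape(n * hp * wp, kh * kw * cout)
            if w.requires_grad:
                dw = (xf.T @ zf).reshape(cin, kh * kw, cout) \
                    .transpose(1, 0, 2).reshape(kh, kw, cin, cout)
                _accum(w, np.ascontiguousarray(dw), own=True)
            if x.requires_grad:
                dxp = (zf @ wcat.T).reshape(n, hp, wp, cin)
                dx = dxp[:, ph:ph + h, pw:pw + wd, :] if ph or pw else dxp
                _accum(x, np.ascontiguousarray(dx), own=True)
        else:
            if w.requires_grad:
                dw = np.empty_like(w.data)
                gp = np.zeros((n, hp, wp, cout), dtype=np.float32)
                for i, j in taps:
                    gp[...] = 0.0
                    gp[:, i:i + h, j:j + wd, :] = g
                    dw[i, j] = xf.T @ gp.reshape(n * hp * wp, cout)
                _accum(w, dw, own=True)
            if x.requires_grad:
                gf = g.reshape(n * h * wd, cout)
                dxp = np.zeros((n, hp, wp, cin), dtype=np.float32)
                for i, j in taps:
                    dxp[:, i:i + h, j:j + wd, :] += \
                        (gf @ w.data[i, j].T).reshape(n, h, wd, cin)
                dx = dxp[:, ph:ph + h, pw:pw + wd, :] if ph or pw else dxp
                _accum(x, np.ascontiguousarray(dx), own=True)
        if b is not None:
            _accum(b, g.sum(axis=(0, 1, 2)), own=True)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor) -> Tensor:
    """Per-channel same-padded 3x3-style convolution; w has shape (kh, kw, c)."""
    kh, kw, c = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("depthwise_conv2d requires odd kernel sizes")
    if x.data.shape[-1] != c:
        raise ValueError("channel mismatch in depthwise convolution")
    ph, pw = kh // 2, kw // 2
    n, h, wd, _ = x.data.shape
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros_like(x.data)
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i:i + h, j:j + wd, :] * w.data[i, j]

    def backward(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[i, j] = np.einsum(
                        "nhwc,nhwc->c", xp[:, i:i + h, j:j + wd, :], g)
            _accum(w, dw, own=True)
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
            dx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    dx += gp[:, i:i + h, j:j + wd, :] * w.data[kh - 1 - i, kw - 1 - j]
            _accum(x, dx, own=True)

    return _make(out, (x, w), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2 transposed convolution with a 2x2 kernel (exact x2 upsampling).

    w has shape (2, 2, cin, cout); output spatial dims are doubled.
    """
    n, h, wd, cin = x.data.shape
    _, _, wcin, cout = w.data.shape
    if wcin != cin:
        raise ValueError("channel mismatch in transposed convolution")
    xmat = x.data.reshape(n * h * wd, cin)
    out = np.empty((n, 2 * h, 2 * wd, cout), dtype=np.float32)
    for i in range(2):
        for j in range(2):
            out[:, i::2, j::2, :] = (xmat @ w.data[i, j]).reshape(n, h, wd, cout)
    if b is not None:
        out += b.data

    def backward(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(2):
                for j in range(2):
                    dw[i, j] = xmat.T @ g[:, i::2, j::2, :].reshape(n * h * wd, cout)
            _accum(w, dw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dx = np.zeros((n * h * wd, cin), dtype=np.float32)
            for i in range(2):
                for j in range(2):
                    dx += g[:, i::2, j::2, :].reshape(n * h * wd, cout) @ w.data[i, j].T
            _accum(x, dx.reshape(n, h, wd, cin), own=True)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# -- spatial resampling ----------------------------------------------------

def _check_even(x: Tensor) -> None:
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"2x2 pooling requires even spatial dims, got {h}x{w}")
    if h < 2 or w < 2:
        raise ValueError("pooling would produce a zero-sized output")


def max_pool2x2(x: Tensor) -> Tensor:
    _check_even(x)
    n, h, w, c = x.data.shape
    xr = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        _accum(x, dx.reshape(n, h, w, c), own=True)

    return _make(np.ascontiguousarray(out), (x,), backward)


def avg_pool2x2(x: Tensor) -> Tensor:
    _check_even(x)
    n, h, w, c = x.data.shape
    out = x.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(g):
        dx = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
        _accum(x, dx, own=True)

    return _make(out.astype(np.float32), (x,), backward)


def upsample2x_nearest(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        n, h, w, c = x.data.shape
        _accum(x, g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)), own=True)

    return _make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    out = x.data.mean(axis=(1, 2))

    def backward(g):
        _accum(x, np.broadcast_to(g[:, None, None, :] / (h * w), x.data.shape))

    return _make(out.astype(np.float32), (x,), backward)


# -- normalisation and heads ----------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalisation over the (batch, height, width) axes.

    Running statistics are plain arrays mutated in place during training;
    they are not part of the autograd graph.
    """
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = gamma.data * xhat + beta.data

    def backward(g):
        c = x.data.shape[-1]
        g2 = g.reshape(-1, c)
        s1 = g2.sum(axis=0)                     # sum g
        s2 = np.einsum("nc,nc->c", g2, xhat.reshape(-1, c))  # sum g*xhat
        _accum(gamma, s2)
        _accum(beta, s1)
        if not x.requires_grad:
            return
        coef = (gamma.data * inv_std).astype(np.float32)
        if training:
            m = x.data.size // c
            dx = g * coef
            dx += xhat * (-coef * s2 / m)
            dx += -coef * s1 / m
            _accum(x, dx, own=True)
        else:
            _accum(x, g * coef, own=True)

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        _accum(x, out * (g - dot), own=True)

    return _make(out, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer class labels."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    ll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    out = np.float32(ll.mean())

    def backward(g):
        dp = p.copy()
        dp[np.arange(n), labels] -= 1.0
        _accum(logits, (float(g) / n) * dp, own=True)

    return _make(np.asarray(out), (logits,), backward)
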