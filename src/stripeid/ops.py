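"""Reverse-mode automatic differentiation over numpy arrays.

All image tensors use NHWC layout (batch, height, width, channels) in
float32.  The op set is exactly what the recognition network needs:
2-D convolution, batch normalization, pooling, elementwise nonlinearities,
channel descriptors for attention gates, dense layers, dropout and a fused
softmax/cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "scale_add", "relu", "sigmoid", "concat",
    "conv2d", "conv1d_channels", "batchnorm", "maxpool2d", "avgpool2d_same",
    "global_avg_pool", "global_max_pool", "channel_mean", "channel_max",
    "dense", "dropout", "softmax", "softmax_cross_entropy",
]


class Tensor:
    """An array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Accumulate gradients into every reachable parent tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _result(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward():
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(out.grad, b.data.shape))

    out = _result(out_data, (a, b), backward)
    return out


def mul(a, b):
    """Broadcast elementwise product (used for attention gating)."""
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward():
        _accum(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _accum(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out = _result(out_data, (a, b), backward)
    return out


def scale_add(x, branch, scale: float):
    """Residual merge ``x + scale * branch``."""
    x, branch = _wrap(x), _wrap(branch)
    out_data = x.data + np.float32(scale) * branch.data

    def backward():
        _accum(x, out.grad)
        _accum(branch, np.float32(scale) * out.grad)

    out = _result(out_data, (x, branch), backward)
    return out


def relu(x):
    x = _wrap(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward():
        _accum(x, out.grad * mask)

    out = _result(out_data, (x,), backward)
    return out


def sigmoid(x):
    x = _wrap(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward():
        _accum(x, out.grad * s * (1.0 - s))

    out = _result(s, (x,), backward)
    return out


def concat(tensors, axis=-1):
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward():
        splits = np.cumsum(sizes)[:-1]
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            _accum(t, g)

    out = _result(out_data, tuple(tensors), backward)
    return out


# ---------------------------------------------------------------------------
# convolution / pooling


def _pad_amount(n, k, stride, padding):
    if padding == "valid":
        return 0, 0
    if stride != 1:
        raise ValueError("'same' padding only supported for stride 1")
    p = k - 1
    return p // 2, p - p // 2


def conv2d(x, w, b=None, stride: int = 1, padding: str = "valid"):
    """2-D cross-correlation; ``x`` NHWC, ``w`` (kh, kw, cin, cout)."""
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    kh, kw, cin, cout = w.data.shape
    n, h, wd, cx = x.data.shape
    if cx != cin:
        raise ValueError(f"conv2d: input has {cx} channels, kernel expects {cin}")
    pt, pb = _pad_amount(h, kh, stride, padding)
    pl, pr = _pad_amount(wd, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if pt or pb or pl or pr else x.data
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: {h}x{wd} input collapses under {kh}x{kw}/s{stride} {padding}")
    out_data = np.zeros((n, ho, wo, cout), dtype=np.float32)
    out_flat = out_data.reshape(-1, cout)
    for a in range(kh):
        for c in range(kw):
            xs = xp[:, a:a + stride * ho:stride, c:c + stride * wo:stride, :]
            out_flat += np.ascontiguousarray(xs).reshape(-1, cin) @ w.data[a, c]
    if b is not None:
        out_data += b.data

    def backward():
        g = out.grad
        gm = g.reshape(-1, cout)
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for a in range(kh):
            for c in range(kw):
                xs = xp[:, a:a + stride * ho:stride, c:c + stride * wo:stride, :]
                if w.requires_grad:
                    _accum_slice_w(w, a, c, xs.reshape(-1, cin).T @ gm)
                if dxp is not None:
                    dxp[:, a:a + stride * ho:stride, c:c + stride * wo:stride, :] += (
                        gm @ w.data[a, c].T).reshape(n, ho, wo, cin)
        if dxp is not None:
            _accum(x, dxp[:, pt:hp - pb or None, pl:wp - pr or None, :]
                   if (pt or pb or pl or pr) else dxp)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 1, 2)))

    out = _result(out_data, (x, w) + ((b,) if b is not None else ()), backward)
    return out


def _accum_slice_w(w: Tensor, a, c, g):
    if w.grad is None:
        w.grad = np.zeros_like(w.data)
    w.grad[a, c] += g


def conv1d_channels(v, w):
    """Same-padded bias-free 1-D convolution along the channel axis.

    ``v`` has shape (n, C) — a pooled channel descriptor; ``w`` shape (k,).
    This is the local cross-channel interaction used by ECA gates.
    """
    v, w = _wrap(v), _wrap(w)
    k = w.data.shape[0]
    p = (k - 1) // 2
    n, c = v.data.shape
    vp = np.pad(v.data, ((0, 0), (p, p)))
    out_data = np.zeros_like(v.data)
    for i in range(k):
        out_data += w.data[i] * vp[:, i:i + c]

    def backward():
        g = out.grad
        if w.requires_grad:
            if w.grad is None:
                w.grad = np.zeros_like(w.data)
            for i in range(k):
                w.grad[i] += float((g * vp[:, i:i + c]).sum())
        if v.requires_grad:
            gp = np.zeros_like(vp)
            for i in range(k):
                gp[:, i:i + c] += w.data[i] * g
            _accum(v, gp[:, p:p + c])

    out = _result(out_data, (v, w), backward)
    return out


def batchnorm(x, beta, state_mean, state_var, training: bool,
              momentum: float = 0.9, eps: float = 1e-3):
    """Scale-free batch normalization: ``(x - mu)/sigma + beta``.

    There is no learnable gamma; ``state_mean``/``state_var`` are plain
    arrays updated in place during training and used verbatim in eval mode.
    """
    x, beta = _wrap(x), _wrap(beta)
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        state_mean *= momentum
        state_mean += (1.0 - momentum) * mu
        state_var *= momentum
        state_var += (1.0 - momentum) * var
    else:
        mu, var = state_mean, state_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = (xhat + beta.data).astype(np.float32)

    def backward():
        g = out.grad
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            if training:
                m = np.prod([x.data.shape[a] for a in axes])
                gm = g.mean(axis=axes)
                gx = g - gm - xhat * (g * xhat).sum(axis=axes) / m
                _accum(x, gx * inv)
            else:
                _accum(x, g * inv)

    out = _result(out_data, (x, beta), backward)
    return out


def maxpool2d(x, k: int = 3, stride: int = 2):
    """Valid max pooling (the Inception reduction pool)."""
    x = _wrap(x)
    n, h, w, c = x.data.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"maxpool: {h}x{w} input collapses under {k}/s{stride}")
    slabs = np.stack([
        x.data[:, a:a + stride * ho:stride, b:b + stride * wo:stride, :]
        for a in range(k) for b in range(k)
    ])
    arg = slabs.argmax(axis=0)
    out_data = slabs.max(axis=0)

    def backward():
        g = out.grad
        dx = np.zeros_like(x.data)
        idx = 0
        for a in range(k):
            for b in range(k):
                mask = arg == idx
                dx[:, a:a + stride * ho:stride, b:b + stride * wo:stride, :] += g * mask
                idx += 1
        _accum(x, dx)

    out = _result(out_data, (x,), backward)
    return out


def avgpool2d_same(x, k: int = 3):
    """Stride-1 same-padded average pooling, zero padding included in the mean."""
    x = _wrap(x)
    n, h, w, c = x.data.shape
    p = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    out_data = np.zeros_like(x.data)
    for a in range(k):
        for b in range(k):
            out_data += xp[:, a:a + h, b:b + w, :]
    out_data /= k * k

    def backward():
        g = out.grad / (k * k)
        gp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                gp[:, a:a + h, b:b + w, :] += g
        _accum(x, gp[:, p:p + h, p:p + w, :])

    out = _result(out_data, (x,), backward)
    return out


def global_avg_pool(x):
    x = _wrap(x)
    n, h, w, c = x.data.shape
    out_data = x.data.mean(axis=(1, 2))

    def backward():
        _accum(x, np.broadcast_to(out.grad[:, None, None, :] / (h * w), x.data.shape).copy())

    out = _result(out_data, (x,), backward)
    return out


def global_max_pool(x):
    x = _wrap(x)
    n, h, w, c = x.data.shape
    flat = x.data.reshape(n, h * w, c)
    arg = flat.argmax(axis=1)
    out_data = np.take_along_axis(flat, arg[:, None, :], axis=1)[:, 0, :]

    def backward():
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[:, None, :], out.grad[:, None, :], axis=1)
        _accum(x, dflat.reshape(x.data.shape))

    out = _result(out_data, (x,), backward)
    return out


def channel_mean(x):
    x = _wrap(x)
    c = x.data.shape[-1]
    out_data = x.data.mean(axis=-1, keepdims=True)

    def backward():
        _accum(x, np.broadcast_to(out.grad / c, x.data.shape).copy())

    out = _result(out_data, (x,), backward)
    return out


def channel_max(x):
    x = _wrap(x)
    arg = x.data.argmax(axis=-1)
    out_data = np.take_along_axis(x.data, arg[..., None], axis=-1)

    def backward():
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, arg[..., None], out.grad, axis=-1)
        _accum(x, dx)

    out = _result(out_data, (x,), backward)
    return out


def dense(x, w, b=None):
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def backward():
        g = out.grad
        _accum(w, x.data.T @ g)
        _accum(x, g @ w.data.T)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=0))

    out = _result(out_data, (x, w) + ((b,) if b is not None else ()), backward)
    return out


def dropout(x, rate: float, rng: np.random.Generator, training: bool):
    """Inverted dropout; identity in eval mode or at rate 0."""
    x = _wrap(x)
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    out_data = x.data * mask

    def backward():
        _accum(x, out.grad * mask)

    out = _result(out_data, (x,), backward)
    return out


def softmax(x):
    x = _wrap(x)
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward():
        g = out.grad
        _accum(x, p * (g - (g * p).sum(axis=-1, keepdims=True)))

    out = _result(p, (x,), backward)
    return out


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy of softmax(logits) against integer labels."""
    logits = _wrap(logits)
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    ll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    out_data = np.float32(ll.mean())

    def backward():
        g = p.copy()
        g[np.arange(n), labels] -= 1.0
        _accum(logits, out.grad * g / n)

    out = _result(out_data, (logits,), backward)
    return out
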