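"""Neural-network operations on channels-last volumetric tensors.

All spatial operators act on arrays of shape ``(B, H, W, D, C)``. Convolutions
are evaluated by looping over the k**3 kernel offsets and accumulating a
channel matmul (dense) or a broadcast multiply (depthwise) over strided
views — this keeps peak memory at O(volume x channels) rather than the
O(volume x channels x k**3) of an im2col lowering, which matters for
whole-volume inference.
"""
from __future__ import annotations

import numpy as np
from scipy.special import erf

from .tensor import Tensor, grad_enabled

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 3D convolution. ``w`` has shape (k, k, k, Cin, Cout)."""
    k = w.shape[0]
    cin, cout = w.shape[3], w.shape[4]
    B, H, W, D, C = x.shape
    if C != cin:
        raise ValueError(f"conv3d: expected {cin} input channels, got {C}")
    s, p = stride, padding
    Ho, Wo, Do = _out_size(H, k, s, p), _out_size(W, k, s, p), _out_size(D, k, s, p)
    xp = _pad_spatial(x.data, p)
    wd = w.data
    out = np.zeros((B, Ho, Wo, Do, cout), dtype=np.float32)
    of = out.reshape(-1, cout)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                xs = xp[:, dx:dx + s * Ho:s, dy:dy + s * Wo:s, dz:dz + s * Do:s, :]
                of += xs.reshape(-1, cin) @ wd[dx, dy, dz]
    if b is not None:
        out += b.data
    req = (x.requires_grad or w.requires_grad
           or (b is not None and b.requires_grad))
    if not (req and grad_enabled()):
        return Tensor(out)
    parents = [t for t in (x, w, b) if t is not None and t.requires_grad]
    res = Tensor(out, True, parents)

    def backward(g):
        gf = g.reshape(-1, cout)
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        need_gx = x.requires_grad
        gxp = np.zeros_like(xp) if need_gx else None
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    xs = xp[:, dx:dx + s * Ho:s, dy:dy + s * Wo:s, dz:dz + s * Do:s, :]
                    if w.requires_grad:
                        w._accumulate_at((dx, dy, dz), xs.reshape(-1, cin).T @ gf)
                    if need_gx:
                        gxp[:, dx:dx + s * Ho:s, dy:dy + s * Wo:s, dz:dz + s * Do:s, :] += (
                            gf @ wd[dx, dy, dz].T).reshape(B, Ho, Wo, Do, cin)
        if need_gx:
            if p:
                gxp = gxp[:, p:-p, p:-p, p:-p, :]
            x._accumulate(gxp)

    res._backward = backward
    return res


def depthwise_conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel (depthwise) 3D convolution. ``w`` has shape (k, k, k, C)."""
    k = w.shape[0]
    B, H, W, D, C = x.shape
    if C != w.shape[3]:
        raise ValueError(f"depthwise_conv3d: expected {w.shape[3]} channels, got {C}")
    s, p = stride, padding
    Ho, Wo, Do = _out_size(H, k, s, p), _out_size(W, k, s, p), _out_size(D, k, s, p)
    xp = _pad_spatial(x.data, p)
    wd = w.data
    out = np.zeros((B, Ho, Wo, Do, C), dtype=np.float32)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                out += xp[:, dx:dx + s * Ho:s, dy:dy + s * Wo:s, dz:dz + s * Do:s, :] * wd[dx, dy, dz]
    if b is not None:
        out += b.data
    req = (x.requires_grad or w.requires_grad
           or (b is not None and b.requires_grad))
    if not (req and grad_enabled()):
        return Tensor(out)
    parents = [t for t in (x, w, b) if t is not None and t.requires_grad]
    res = Tensor(out, True, parents)

    def backward(g):
        gf = g.reshape(-1, C)
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        need_gx = x.requires_grad
        gxp = np.zeros_like(xp) if need_gx else None
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    xs = xp[:, dx:dx + s * Ho:s, dy:dy + s * Wo:s, dz:dz + s * Do:s, :]
                    if w.requires_grad:
                        w._accumulate_at((dx, dy, dz),
                                         np.einsum("bhwdc,bhwdc->c", xs, g))
                    if need_gx:
                        gxp[:, dx:dx + s * Ho:s, dy:dy + s * Wo:s, dz:dz + s * Do:s, :] += g * wd[dx, dy, dz]
        if need_gx:
            if p:
                gxp = gxp[:, p:-p, p:-p, p:-p, :]
            x._accumulate(gxp)

    res._backward = backward
    return res


def pointwise_conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1x1x1 convolution = channel matmul. ``w`` has shape (Cin, Cout)."""
    B, H, W, D, C = x.shape
    out = x.reshape(-1, C).matmul(w)
    if b is not None:
        out = out + b
    return out.reshape(B, H, W, D, w.shape[1])


def zero_stuff(x: Tensor, s: int) -> Tensor:
    """Insert s-1 zeros between spatial samples (transposed-conv lowering)."""
    B, H, W, D, C = x.shape
    out = np.zeros((B, s * (H - 1) + 1, s * (W - 1) + 1, s * (D - 1) + 1, C),
                   dtype=np.float32)
    out[:, ::s, ::s, ::s, :] = x.data
    if not (x.requires_grad and grad_enabled()):
        return Tensor(out)
    res = Tensor(out, True, (x,))
    res._backward = lambda g: x._accumulate(g[:, ::s, ::s, ::s, :])
    return res


def max_pool3d(x: Tensor, r: int) -> Tensor:
    """Non-overlapping max pooling with kernel = stride = r."""
    B, H, W, D, C = x.shape
    if H % r or W % r or D % r:
        raise ValueError(f"max_pool3d: dims {(H, W, D)} not divisible by r={r}")
    Ho, Wo, Do = H // r, W // r, D // r
    xt = (x.data.reshape(B, Ho, r, Wo, r, Do, r, C)
          .transpose(0, 1, 3, 5, 7, 2, 4, 6)
          .reshape(B, Ho, Wo, Do, C, r ** 3))
    idx = xt.argmax(axis=-1)
    out = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
    if not (x.requires_grad and grad_enabled()):
        return Tensor(out)
    res = Tensor(out, True, (x,))

    def backward(g):
        gt = np.zeros((B, Ho, Wo, Do, C, r ** 3), dtype=np.float32)
        np.put_along_axis(gt, idx[..., None], g[..., None], axis=-1)
        gx = (gt.reshape(B, Ho, Wo, Do, C, r, r, r)
              .transpose(0, 1, 5, 2, 6, 3, 7, 4)
              .reshape(B, H, W, D, C))
        x._accumulate(gx)

    res._backward = backward
    return res


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd / _SQRT2))
    out = xd * cdf
    if not (x.requires_grad and grad_enabled()):
        return Tensor(out)
    res = Tensor(out, True, (x,))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * xd * xd)
        x._accumulate(g * (cdf + xd * pdf).astype(np.float32))

    res._backward = backward
    return res


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))
    if not (x.requires_grad and grad_enabled()):
        return Tensor(out)
    res = Tensor(out, True, (x,))
    res._backward = lambda g: x._accumulate(g * out * (1.0 - out))
    return res


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)
    if not (x.requires_grad and grad_enabled()):
        return Tensor(out)
    res = Tensor(out, True, (x,))

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - dot))

    res._backward = backward
    return res


def layer_norm(x: Tensor, gain: Tensor, offset: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalize over the trailing channel axis (per voxel)."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gain.data + offset.data
    req = x.requires_grad or gain.requires_grad or offset.requires_grad
    if not (req and grad_enabled()):
        return Tensor(out)
    parents = [t for t in (x, gain, offset) if t.requires_grad]
    res = Tensor(out, True, parents)

    def backward(g):
        C = xd.shape[-1]
        if offset.requires_grad:
            offset._accumulate(g.reshape(-1, C).sum(axis=0))
        if gain.requires_grad:
            gain._accumulate((g * xhat).reshape(-1, C).sum(axis=0))
        if x.requires_grad:
            gh = g * gain.data
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(((gh - m1 - xhat * m2) * inv).astype(np.float32))

    res._backward = backward
    return res


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[-1]
    out = np.concatenate([a.data, b.data], axis=-1)
    req = a.requires_grad or b.requires_grad
    if not (req and grad_enabled()):
        return Tensor(out)
    res = Tensor(out, True, [t for t in (a, b) if t.requires_grad])

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[..., :ca])
        if b.requires_grad:
            b._accumulate(g[..., ca:])

    res._backward = backward
    return res


def pad_spatial(x: Tensor, pads: tuple[tuple[int, int], ...]) -> Tensor:
    """Symmetric-style explicit zero pad of the three spatial axes."""
    width = ((0, 0), *pads, (0, 0))
    out = np.pad(x.data, width)
    if not (x.requires_grad and grad_enabled()):
        return Tensor(out)
    res = Tensor(out, True, (x,))

    def backward(g):
        sl = tuple(slice(lo, g.shape[i + 1] - hi if hi else None)
                   for i, (lo, hi) in enumerate(pads))
        x._accumulate(g[(slice(None),) + sl + (slice(None),)])

    res._backward = backward
    return res


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float32)
    if z.shape != y.shape:
        raise ValueError(f"bce_with_logits: shape mismatch {z.shape} vs {y.shape}")
    loss_el = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = np.float32(loss_el.mean(dtype=np.float64))
    if not (logits.requires_grad and grad_enabled()):
        return Tensor(loss)
    res = Tensor(loss, True, (logits,))

    def backward(g):
        p = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate((g * (p - y) / z.size).astype(np.float32))

    res._backward = backward
    return res
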