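"""Structured primitives: 2-D convolution (im2col) and nearest upsampling."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "upsample_nearest", "max_pool2d"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (b, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(view).reshape(b, c * kh * kw, ho * wo), ho, wo


def _col2im(dcol: np.ndarray, xshape, kh, kw, stride, pad):
    b, c, h, w = xshape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    d6 = dcol.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[
                :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with (out, in, kh, kw) kernels."""
    cout, cin, kh, kw = w.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, kernel expects {cin}")
    col, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, col)  # (b, cout, ho*wo) via broadcasting
    if b is not None:
        out = out + b.data.reshape(1, cout, 1)
    nb = x.data.shape[0]
    xshape = x.data.shape

    def backward(g, x=x, w=w, b=b, col=col, wmat=wmat):
        g2 = g.reshape(nb, cout, ho * wo)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=(0, 2)))
        if w.requires_grad:
            dw = np.einsum("bop,bkp->ok", g2, col)
            w._accum(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcol = np.matmul(wmat.T, g2)  # (b, cin*kh*kw, ho*wo)
            x._accum(_col2im(dcol, xshape, kh, kw, stride, padding))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out.reshape(nb, cout, ho, wo), parents, backward)


def max_pool2d(x: Tensor, k: int, stride: int = 1, padding: int | None = None) -> Tensor:
    """Spatial max pooling; same-size by default (stride 1, pad k//2)."""
    pad = k // 2 if padding is None else padding
    b, c, h, w = x.data.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (b, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    out = view.max(axis=(2, 3))
    mask = view == out[:, :, None, None, :, :]
    counts = mask.sum(axis=(2, 3))

    def backward(g, x=x):
        if not x.requires_grad:
            return
        contrib = mask * (g / counts)[:, :, None, None, :, :]
        dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    contrib[:, :, i, j]
                )
        x._accum(dxp[:, :, pad : pad + h, pad : pad + w])

    return Tensor._make(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    y = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    b, c, h, w = x.data.shape

    def backward(g, x=x):
        if x.requires_grad:
            g6 = g.reshape(b, c, h, factor, w, factor)
            x._accum(g6.sum(axis=(3, 5)))

    return Tensor._make(y, (x,), backward)
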