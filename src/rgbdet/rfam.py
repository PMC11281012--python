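"""Rough-Fine Hybrid Attention Fusion Module (RFAM).

RFAM fuses aligned RGB and depth feature grids in two granularities:

*Rough (coarse) fusion* — both grids are flattened to spatial-token
sequences and cross-attention is computed in both directions (RGB queries
attend depth and vice versa), semantically filling each modality's gaps
(depth voids, light-polluted RGB) from the other.  Two independent
bottleneck MLPs then transform the attended sequences, which are reshaped
back into grids ``RGB_R`` and ``Depth_R``.

*Fine fusion* — coordinate-attention style: each coarse grid is max-pooled
along height and along width into directional profiles ``(b,c,w,1)`` and
``(b,c,1,h)``; the four profiles are spliced into one mixed vector of
length ``2w + 2h``, transformed by a shared MLP, split back (splice and
split are exact inverses when the MLP is the identity), and finally each
coarse grid is re-weighted by its own two profiles and the two streams are
summed:

    Fused = RGB_R * RGB_w * RGB_h  +  Depth_R * Depth_w * Depth_h

The profile products are realised as broadcast multiplication across the
collapsed axis (standard coordinate-attention semantics); a literal
matrix-product variant and a sigmoid-bounded variant are available as
flags for experimentation.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .lgem import _as4d, flatten_tokens, upsample_tokens
from .lgem import LocalMLP as BottleneckMLP
from .nn import Tensor

__all__ = [
    "cross_attention",
    "coarse_fuse",
    "directional_pool",
    "mix_vectors",
    "split_vectors",
    "fine_fuse",
    "RFAM",
    "TriRFAM",
    "rfam_forward",
    "rfam_forward_tri",
]


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def cross_attention(rgb: np.ndarray, depth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bidirectional cross-attention between two aligned grids.

    Returns token sequences ``(Attention1, Attention2)`` where
    ``Attention1 = softmax(q1 k2^T / sqrt(d_k)) v2`` (RGB queries attend
    depth) and symmetrically for ``Attention2``.  ``d_k`` is the channel
    count of the flattened tokens.
    """
    rgb, depth = _as4d(rgb, "rgb"), _as4d(depth, "depth")
    if rgb.shape != depth.shape:
        raise ValueError(f"shape mismatch: rgb {rgb.shape} vs depth {depth.shape}")
    b, c, h, w = rgb.shape
    t1 = flatten_tokens(rgb)[:, 0].transpose(0, 2, 1)  # (b, n, c)
    t2 = flatten_tokens(depth)[:, 0].transpose(0, 2, 1)

    def attend(q, k, v):
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(c)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=-1, keepdims=True)
        return (a @ v).transpose(0, 2, 1).reshape(b, 1, c, h * w)

    return attend(t1, t2, t2), attend(t2, t1, t1)


def coarse_fuse(mlp: BottleneckMLP, attn: np.ndarray, h: int, w: int) -> np.ndarray:
    """Transform an attended token sequence and reshape it into a grid.

    The bottleneck MLP (convolutions over the flattened vector treated as a
    column image) runs first; Reshape — the inverse of Flatten — restores
    (b, c, h, w).  The RGB-side and depth-side MLPs are independent
    instances.
    """
    t = np.asarray(attn, dtype=np.float64)
    if t.ndim != 4 or t.shape[1] != 1:
        raise ValueError(f"token sequence must be (b, 1, c, n), got {t.shape}")
    b, _, c, n = t.shape
    if c % 2 != 0:
        raise ValueError(f"channel count must be even for the c/2 bottleneck, got {c}")
    if n != h * w:
        raise ValueError(f"token count {n} != h*w = {h * w}")
    col = t.reshape(b, c, n, 1)  # column-vector image for the convolutional MLP
    y = mlp(Tensor(col)).data
    return upsample_tokens(y.reshape(b, 1, c, n), h, w)


def directional_pool(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max-pool a grid along each spatial axis into directional profiles.

    Returns the width profile (max over height, shape ``(b,c,w,1)``) and
    the height profile (max over width, shape ``(b,c,1,h)``).
    """
    g = _as4d(grid, "grid")
    b, c, h, w = g.shape
    prof_w = g.max(axis=2).reshape(b, c, w, 1)
    prof_h = g.max(axis=3).reshape(b, c, 1, h)
    return prof_w, prof_h


def mix_vectors(rgbw: np.ndarray, depthw: np.ndarray,
                rgbh: np.ndarray, depthh: np.ndarray) -> np.ndarray:
    """Splice the four directional profiles into one mixed vector.

    Height profiles are transposed (last two dims swapped) first; the
    concatenation order is fixed: ``[RGB_w | Depth_w | T(RGB_h) | T(Depth_h)]``
    giving shape (b, c, 2w+2h, 1).
    """
    rgbw, depthw = _as4d(rgbw, "rgbw"), _as4d(depthw, "depthw")
    rgbh, depthh = _as4d(rgbh, "rgbh"), _as4d(depthh, "depthh")
    if rgbw.shape != depthw.shape or rgbh.shape != depthh.shape:
        raise ValueError("profile shape mismatch between modalities")
    if rgbw.shape[:2] != rgbh.shape[:2]:
        raise ValueError(
            f"batch/channel mismatch: {rgbw.shape[:2]} vs {rgbh.shape[:2]}"
        )
    if rgbw.shape[3] != 1 or rgbh.shape[2] != 1:
        raise ValueError("expected width profiles (b,c,w,1) and height profiles (b,c,1,h)")
    t_rgbh = rgbh.transpose(0, 1, 3, 2)
    t_depthh = depthh.transpose(0, 1, 3, 2)
    return np.concatenate([rgbw, depthw, t_rgbh, t_depthh], axis=2)


def split_vectors(mixed: np.ndarray, w: int, h: int,
                  mlp: BottleneckMLP | None = None):
    """Transform the mixed vector and split it back into four profiles.

    A single shared bottleneck MLP (same structure as the coarse-fusion
    one) is applied to the (b, c, 2w+2h, 1) vector; ``mlp=None`` means the
    identity, under which split is the exact inverse of
    :func:`mix_vectors`.  Height profiles are un-transposed on the way
    out.
    """
    m = _as4d(mixed, "mixed")
    if m.shape[2] != 2 * w + 2 * h:
        raise ValueError(f"mixed length {m.shape[2]} != 2w+2h = {2 * w + 2 * h}")
    if m.shape[3] != 1:
        raise ValueError(f"mixed vector must have trailing extent 1, got {m.shape}")
    if mlp is not None:
        m = mlp(Tensor(m)).data
    rgbw = m[:, :, :w, :]
    depthw = m[:, :, w : 2 * w, :]
    rgbh = m[:, :, 2 * w : 2 * w + h, :].transpose(0, 1, 3, 2)
    depthh = m[:, :, 2 * w + h :, :].transpose(0, 1, 3, 2)
    return rgbw, depthw, rgbh, depthh


def fine_fuse(rgbR: np.ndarray, depthR: np.ndarray,
              rgbw: np.ndarray, rgbh: np.ndarray,
              depthw: np.ndarray, depthh: np.ndarray,
              bounded: bool = False, literal_matmul: bool = False) -> np.ndarray:
    """Coordinate-attention fine fusion of the two coarse grids.

    ``Fused = RGB_R * RGB_w * RGB_h + Depth_R * Depth_w * Depth_h`` with
    each directional profile broadcast across its collapsed axis, output
    shape (b, c, h, w).  ``bounded=True`` squashes the profiles through a
    sigmoid first (classic coordinate attention); ``literal_matmul=True``
    chains true matrix products instead of broadcasting (requires h == w
    for the two streams to be summable) — kept for experimentation only.
    """
    rgbR, depthR = _as4d(rgbR, "rgbR"), _as4d(depthR, "depthR")
    b, c, h, w = rgbR.shape
    if depthR.shape != rgbR.shape:
        raise ValueError(f"coarse grid mismatch: {rgbR.shape} vs {depthR.shape}")
    for name, p, shape in (("rgbw", rgbw, (b, c, w, 1)), ("depthw", depthw, (b, c, w, 1)),
                           ("rgbh", rgbh, (b, c, 1, h)), ("depthh", depthh, (b, c, 1, h))):
        if np.asarray(p).shape != shape:
            raise ValueError(f"{name} must have shape {shape}, got {np.asarray(p).shape}")
    profs = [np.asarray(p, dtype=np.float64) for p in (rgbw, rgbh, depthw, depthh)]
    if bounded:
        profs = [1.0 / (1.0 + np.exp(-p)) for p in profs]
    rgbw, rgbh, depthw, depthh = profs
    if literal_matmul:
        out = rgbR @ rgbw @ rgbh + depthR @ depthw @ depthh
        return out
    # broadcast: width profile varies along w, height profile along h
    return (rgbR * rgbw.transpose(0, 1, 3, 2) * rgbh.transpose(0, 1, 3, 2)
            + depthR * depthw.transpose(0, 1, 3, 2) * depthh.transpose(0, 1, 3, 2))


# ---------------------------------------------------------------------------
# trainable block
# ---------------------------------------------------------------------------

class RFAM(nn.Module):
    """Rough-fine fusion block for a pair of aligned feature grids.

    Parameters
    ----------
    channels:
        Channel count ``c`` of both input grids; must be even for the
        ``c/2`` bottleneck of the MLPs.
    bounded:
        Sigmoid-squash the fine-fusion profiles (off by default; the
        equations carry no sigmoid).
    """

    def __init__(self, channels: int, bounded: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if channels % 2 != 0 or channels < 2:
            raise ValueError(f"channels must be even and >= 2, got {channels}")
        self.channels = channels
        self.bounded = bounded
        c = channels
        # two mutually independent coarse MLPs + one shared mixed-vector MLP
        self.mlp_rgb = BottleneckMLP(c, c // 2, c, rng=rng)
        self.mlp_depth = BottleneckMLP(c, c // 2, c, rng=rng)
        self.mlp_mixed = BottleneckMLP(c, c // 2, c, rng=rng)

    def forward(self, rgb: Tensor, depth: Tensor) -> Tensor:
        if rgb.shape != depth.shape:
            raise ValueError(f"shape mismatch: rgb {rgb.shape} vs depth {depth.shape}")
        b, c, h, w = rgb.shape
        if c != self.channels:
            raise ValueError(f"block built for {self.channels} channels, got {c}")
        n = h * w
        t1 = rgb.reshape(b, c, n).transpose((0, 2, 1))  # (b, n, c)
        t2 = depth.reshape(b, c, n).transpose((0, 2, 1))
        scale = 1.0 / np.sqrt(c)
        a1 = ((t1 @ t2.transpose((0, 2, 1))) * scale).softmax(axis=-1) @ t2
        a2 = ((t2 @ t1.transpose((0, 2, 1))) * scale).softmax(axis=-1) @ t1
        # coarse fusion: independent MLPs over the flattened column image
        rgbR = self.mlp_rgb(a1.transpose((0, 2, 1)).reshape(b, c, n, 1)).reshape(b, c, h, w)
        depthR = self.mlp_depth(a2.transpose((0, 2, 1)).reshape(b, c, n, 1)).reshape(b, c, h, w)
        # directional pooling
        rgbw = rgbR.max(axis=2, keepdims=True).transpose((0, 1, 3, 2))   # (b,c,w,1)
        rgbh = rgbR.max(axis=3, keepdims=True).transpose((0, 1, 3, 2))   # (b,c,1,h)
        depthw = depthR.max(axis=2, keepdims=True).transpose((0, 1, 3, 2))
        depthh = depthR.max(axis=3, keepdims=True).transpose((0, 1, 3, 2))
        mixed = nn.concatenate(
            [rgbw, depthw, rgbh.transpose((0, 1, 3, 2)), depthh.transpose((0, 1, 3, 2))],
            axis=2,
        )
        mixed = self.mlp_mixed(mixed)
        rgbw = mixed[:, :, :w, :]
        depthw = mixed[:, :, w:2 * w, :]
        rgbh = mixed[:, :, 2 * w:2 * w + h, :].transpose((0, 1, 3, 2))
        depthh = mixed[:, :, 2 * w + h:, :].transpose((0, 1, 3, 2))
        if self.bounded:
            rgbw, rgbh = rgbw.sigmoid(), rgbh.sigmoid()
            depthw, depthh = depthw.sigmoid(), depthh.sigmoid()
        return (rgbR * rgbw.transpose((0, 1, 3, 2)) * rgbh.transpose((0, 1, 3, 2))
                + depthR * depthw.transpose((0, 1, 3, 2)) * depthh.transpose((0, 1, 3, 2)))


def rfam_forward(block: RFAM, rgb: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """NumPy-level full RFAM pass: fused grid with the input shape."""
    return block(Tensor(_as4d(rgb, "rgb")), Tensor(_as4d(depth, "depth"))).data


class TriRFAM(nn.Module):
    """Three-stream fusion ``f = RFAM_outer(RFAM_xy(x, y), RFAM_xz(x, z))``.

    Three RFAM instances with their own parameters; the first modality
    (typically RGB) anchors both inner fusions.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.inner_xy = RFAM(channels, rng=rng)
        self.inner_xz = RFAM(channels, rng=rng)
        self.outer = RFAM(channels, rng=rng)

    def forward(self, x: Tensor, y: Tensor, z: Tensor) -> Tensor:
        return self.outer(self.inner_xy(x, y), self.inner_xz(x, z))


def rfam_forward_tri(block: TriRFAM, x: np.ndarray, y: np.ndarray,
                     z: np.ndarray) -> np.ndarray:
    return block(Tensor(_as4d(x, "x")), Tensor(_as4d(y, "y")), Tensor(_as4d(z, "z"))).data
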