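"""Local-Global Enhancement Module (LGEM).

LGEM jointly enhances the two modality streams of a dual-stream RGB-D
backbone.  The idea: depth imagery is robust to lighting, so a weight map
distilled from the *mixed* modalities can restore RGB features polluted by
glare or darkness.  The block proceeds in two granularities:

1. *Local*: the RGB and depth grids are concatenated on channels and a
   small convolutional MLP compresses the mix to a one-channel local
   weight map ``E_local`` (b, 1, h, w).
2. *Global*: ``E_local`` is flattened to a token sequence, passed through
   single-head self-attention over spatial positions (giving every pixel a
   global receptive field), reshaped back, refined by a miniature 1x1
   convolution into ``E_global``, and finally both streams are multiplied
   elementwise by the broadcast weight map.

Two surfaces are provided: pure-NumPy functional operations (used by the
tests' independent oracles and by anyone wanting the raw math), and the
trainable :class:`LGEM` block over autograd tensors used in the backbone.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "concat_modalities",
    "local_mlp",
    "flatten_tokens",
    "upsample_tokens",
    "self_attention",
    "global_weight",
    "enhance",
    "LocalMLP",
    "LGEM",
    "lgem_forward",
    "lgem_forward_tri",
]


def _as4d(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"{name} must be a (b, c, h, w) grid, got shape {x.shape}")
    return x


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def concat_modalities(*grids: np.ndarray) -> np.ndarray:
    """Concatenate aligned modality grids on the channel axis.

    With two arguments this is ``Local = concat(RGB, Depth)``; three
    arguments give the tri-modal variant ``concat(x, y, z)``.  Channel
    blocks keep the argument order.
    """
    arrs = [_as4d(g, f"grid[{i}]") for i, g in enumerate(grids)]
    if len(arrs) < 2:
        raise ValueError("need at least two modality grids")
    first = arrs[0].shape
    for i, a in enumerate(arrs[1:], 1):
        if a.shape != first:
            raise ValueError(
                f"modality shape mismatch: grid[0] is {first} but grid[{i}] is {a.shape}"
            )
    return np.concatenate(arrs, axis=1)


def flatten_tokens(grid: np.ndarray) -> np.ndarray:
    """Reshape a (b, c, h, w) grid into a token sequence (b, 1, c, h*w).

    Tokens are spatial positions; the feature axis is the channel axis.
    Pure reshape: no value changes, and :func:`upsample_tokens` inverts it
    bit-exactly.
    """
    g = _as4d(grid, "grid")
    b, c, h, w = g.shape
    return g.reshape(b, 1, c, h * w)


def upsample_tokens(tokens: np.ndarray, h: int, w: int) -> np.ndarray:
    """Inverse of :func:`flatten_tokens`: (b, 1, c, h*w) -> (b, c, h, w)."""
    t = np.asarray(tokens, dtype=np.float64)
    if t.ndim != 4 or t.shape[1] != 1:
        raise ValueError(f"token sequence must be (b, 1, c, h*w), got {t.shape}")
    b, _, c, n = t.shape
    if n != h * w:
        raise ValueError(f"token count {n} does not match h*w = {h}*{w} = {h * w}")
    return t.reshape(b, c, h, w)


def self_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention over spatial-position tokens.

    ``q``, ``k``, ``v`` are (b, 1, c, n) token sequences; the output is
    ``softmax(q . k^T / sqrt(d_k)) . v`` with the softmax over the key
    tokens and ``d_k`` the feature (channel) dimension.  Every softmax row
    sums to 1.
    """
    q, k, v = (np.asarray(x, dtype=np.float64) for x in (q, k, v))
    if not (q.shape == k.shape == v.shape):
        raise ValueError(f"q/k/v shape mismatch: {q.shape}, {k.shape}, {v.shape}")
    if q.ndim != 4 or q.shape[1] != 1:
        raise ValueError(f"token sequences must be (b, 1, c, n), got {q.shape}")
    b, _, c, n = q.shape
    Q = q[:, 0].transpose(0, 2, 1)  # (b, n, c): one row per token
    K = k[:, 0].transpose(0, 2, 1)
    V = v[:, 0].transpose(0, 2, 1)
    scores = Q @ K.transpose(0, 2, 1) / np.sqrt(c)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    out = attn @ V  # (b, n, c)
    return out.transpose(0, 2, 1).reshape(b, 1, c, n)


def global_weight(attn: np.ndarray, h: int, w: int,
                  weight: np.ndarray | float = 1.0,
                  bias: float = 0.0) -> np.ndarray:
    """Upsample an attended token sequence into the global weight map.

    The sequence is reshaped back to (b, 1, h, w) (Upsample is the inverse
    of Flatten) and then refined by a miniature 1-in/1-out 1x1 convolution
    with scalar ``weight`` and ``bias``; the defaults make the convolution
    the identity.
    """
    grid = upsample_tokens(attn, h, w)
    if grid.shape[1] != 1:
        raise ValueError(f"global weight map must have 1 channel, got {grid.shape[1]}")
    return grid * float(np.asarray(weight).reshape(())) + bias


def enhance(rgb: np.ndarray, depth: np.ndarray,
            eglobal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicatively enhance both streams with the global weight map.

    ``RGB_E = RGB * E_global`` and ``Depth_E = Depth * E_global`` with the
    single weight channel broadcast across all feature channels.
    """
    rgb, depth = _as4d(rgb, "rgb"), _as4d(depth, "depth")
    e = _as4d(eglobal, "eglobal")
    if e.shape[1] != 1:
        raise ValueError(f"eglobal must have exactly 1 channel, got {e.shape[1]}")
    if e.shape[2:] != rgb.shape[2:] or e.shape[2:] != depth.shape[2:]:
        raise ValueError(
            f"spatial mismatch: eglobal {e.shape[2:]}, rgb {rgb.shape[2:]}, "
            f"depth {depth.shape[2:]}"
        )
    return rgb * e, depth * e


# ---------------------------------------------------------------------------
# trainable blocks
# ---------------------------------------------------------------------------

class LocalMLP(nn.Module):
    """Convolutional bottleneck MLP compressing channels ``cin -> cout``.

    Main branch: Conv(cin->mid) -> Conv(mid->mid) -> ReLU -> Conv(mid->cout)
    -> LayerNorm; residual branch: Conv(cin->cout); output is their
    elementwise sum (layer normalisation applies to the main branch only).
    All convolutions are 3x3, stride 1, padding 1, with bias.
    """

    def __init__(self, cin: int, mid: int, cout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if mid < 1:
            raise ValueError(f"bottleneck width must be >= 1, got {mid}")
        self.conv1 = nn.Conv2d(cin, mid, 3, rng=rng)
        self.conv2 = nn.Conv2d(mid, mid, 3, rng=rng)
        self.conv3 = nn.Conv2d(mid, cout, 3, rng=rng)
        self.norm = nn.LayerNorm(cout)
        self.residual = nn.Conv2d(cin, cout, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        main = self.norm(self.conv3(self.conv2(self.conv1(x)).relu()))
        return main + self.residual(x)


def local_mlp(mlp: LocalMLP, local: np.ndarray) -> np.ndarray:
    """Run a compression MLP over a mixed-modality grid (NumPy in/out).

    The grid's channel count must be even (it is a concatenation of equally
    wide streams); the result is the one-channel local weight map.
    """
    x = _as4d(local, "local")
    if x.shape[1] % 2 != 0 or x.shape[1] < 2:
        raise ValueError(f"mixed grid channel count must be even and >= 2, got {x.shape[1]}")
    return mlp(Tensor(x)).data


class LGEM(nn.Module):
    """Local-Global Enhancement block for ``n_streams`` aligned streams.

    Parameters
    ----------
    channels:
        Per-stream channel count ``c``; must be even so the compression
        MLP's ``c/2`` bottleneck is defined.
    n_streams:
        2 for RGB+Depth, 3 for the tri-modal extension (the MLP input
        width becomes ``3c``; everything else is unchanged).
    """

    def __init__(self, channels: int, n_streams: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if channels % 2 != 0 or channels < 2:
            raise ValueError(f"per-stream channels must be even and >= 2, got {channels}")
        if n_streams not in (2, 3):
            raise ValueError("LGEM supports 2 or 3 streams")
        self.channels = channels
        self.n_streams = n_streams
        self.mlp = LocalMLP(n_streams * channels, channels // 2, 1, rng=rng)
        # miniature MLP of the global branch: a bare 1x1 convolution.
        # Initialised so E_global starts near 1 (identity enhancement):
        # a zero-mean random gate would sign-flip features and stall
        # early training.
        self.refine = nn.Conv2d(1, 1, 1, rng=rng)
        self.refine.weight.data = np.full((1, 1, 1, 1), 0.1)
        self.refine.bias.data = np.ones(1)

    def forward(self, *streams: Tensor) -> tuple[Tensor, ...]:
        if len(streams) != self.n_streams:
            raise ValueError(f"expected {self.n_streams} streams, got {len(streams)}")
        shape = streams[0].shape
        for i, s in enumerate(streams[1:], 1):
            if s.shape != shape:
                raise ValueError(f"stream shape mismatch: {shape} vs {s.shape} (stream {i})")
        b, c, h, w = shape
        if c != self.channels:
            raise ValueError(f"block built for {self.channels} channels, got {c}")
        local = nn.concatenate(list(streams), axis=1)
        elocal = self.mlp(local)  # (b, 1, h, w)
        assert elocal.shape[1] == 1, "local weight map must be single-channel"
        tokens = elocal.reshape(b, h * w, 1)  # spatial tokens, feature dim 1
        scores = (tokens @ tokens.transpose((0, 2, 1))) * (1.0 / np.sqrt(1.0))
        attn = scores.softmax(axis=-1) @ tokens  # (b, h*w, 1)
        eglobal = self.refine(attn.reshape(b, 1, h, w))
        assert eglobal.shape[1] == 1, "global weight map must be single-channel"
        return tuple(s * eglobal for s in streams)


def lgem_forward(block: LGEM, rgb: np.ndarray, depth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NumPy-level full LGEM pass: returns the two enhanced streams."""
    out = block(Tensor(_as4d(rgb, "rgb")), Tensor(_as4d(depth, "depth")))
    return out[0].data, out[1].data


def lgem_forward_tri(block: LGEM, x: np.ndarray, y: np.ndarray,
                     z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tri-modal LGEM pass; ``block`` must have been built with 3 streams."""
    out = block(Tensor(_as4d(x, "x")), Tensor(_as4d(y, "y")), Tensor(_as4d(z, "z")))
    return out[0].data, out[1].data, out[2].data
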