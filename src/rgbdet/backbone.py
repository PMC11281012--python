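"""Configurable dual/tri-stream detection scaffold.

The scaffold wires the fusion blocks into a complete anchor-free detector:
one weight-independent feature-extraction stack per modality (simplified
residual-conv stages, three of them, at strides 8/16/32), an LGEM
embedded at each stage to cross-enhance the streams, an RFAM fusing each
stage's outputs into a single pyramid, a small pooling-and-merge neck, a
prediction head per scale, and — optionally — an RGB auxiliary flow
(pass-through placeholder -> CBLinear channel splits -> CBFuse merges)
that adds gradient signal during training and is skipped at inference.

The stage blocks are deliberately simple residual stacks, not replicas of
any particular published backbone: the scaffold's contract is
topological (stages, embeddings, auxiliary flow), and every piece is
sized by :class:`ModelConfig` so desk-scale models train on a CPU.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .lgem import LGEM
from .nn import Tensor
from .rfam import RFAM, TriRFAM

__all__ = [
    "ModelConfig",
    "DualStreamDetector",
    "build_model",
    "count_params",
    "enumerate_conv_fc_params",
    "measure_speed",
    "save_checkpoint",
    "load_checkpoint",
]

SCALE_MULTIPLIERS = {"s": 0.25, "m": 0.5, "l": 1.0}
STRIDES = (8, 16, 32)
MODALITY_CHANNELS = (3, 1, 1)  # rgb, depth, ir


def _even(x: float) -> int:
    v = max(2, int(round(x)))
    return v if v % 2 == 0 else v + 1


@dataclass(frozen=True)
class ModelConfig:
    """Channel plan and switches of the detector.

    ``stage_channels`` must be strictly increasing (channels expand stage
    by stage); ``scale`` applies the s/m/l width multiplier (0.25/0.5/1.0)
    on top, rounded to even so the fusion blocks' ``c/2`` bottlenecks stay
    defined.  Input dimensions must be divisible by the total stride 32.
    """

    stage_channels: tuple[int, int, int] = (16, 24, 32)
    stage_depth: int = 1
    num_classes: int = 4
    input_size: tuple[int, int] = (128, 128)
    modalities: int = 2
    scale: str = "l"
    use_lgem: bool = True
    use_rfam: bool = True
    use_aux: bool = False
    head_channels: int = 16

    def __post_init__(self):
        if list(self.stage_channels) != sorted(set(self.stage_channels)):
            raise ValueError(f"stage_channels must be strictly increasing: {self.stage_channels}")
        if len(self.stage_channels) != 3:
            raise ValueError("exactly three stages (strides 8/16/32) are supported")
        if self.num_classes < 1:
            raise ValueError(f"num_classes must be >= 1, got {self.num_classes}")
        if self.input_size[0] % 32 or self.input_size[1] % 32:
            raise ValueError(f"input size {self.input_size} not divisible by total stride 32")
        if self.modalities not in (2, 3):
            raise ValueError("modalities must be 2 (RGB+D) or 3 (RGB+D+IR)")
        if self.scale not in SCALE_MULTIPLIERS:
            raise ValueError(f"scale must be one of {sorted(SCALE_MULTIPLIERS)}")
        if self.stage_depth < 1:
            raise ValueError("stage_depth must be >= 1")

    @property
    def effective_channels(self) -> tuple[int, int, int]:
        m = SCALE_MULTIPLIERS[self.scale]
        return tuple(_even(c * m) for c in self.stage_channels)

    @property
    def effective_head(self) -> int:
        return _even(self.head_channels * SCALE_MULTIPLIERS[self.scale])


class ResBlock(nn.Module):
    def __init__(self, c: int, rng):
        self.conv1 = nn.Conv2d(c, c, 3, rng=rng)
        self.conv2 = nn.Conv2d(c, c, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).silu())


class Stream(nn.Module):
    """One modality's feature extractor: stem (stride 4) + three stages."""

    def __init__(self, in_ch: int, chans, depth: int, rng):
        stem_ch = max(2, chans[0] // 2)
        self.stem = nn.Sequential(
            nn.Conv2d(in_ch, stem_ch, 3, stride=2, rng=rng), nn.SiLU(),
            nn.Conv2d(stem_ch, stem_ch, 3, stride=2, rng=rng), nn.SiLU(),
        )
        self.stages = []
        prev = stem_ch
        for c in chans:
            # layer norm keeps stage activations bounded so the
            # multiplicative fusion weights downstream stay stable
            mods = [nn.Conv2d(prev, c, 3, stride=2, rng=rng), nn.SiLU()]
            mods += [ResBlock(c, rng) for _ in range(depth)]
            mods.append(nn.LayerNorm(c))
            self.stages.append(nn.Sequential(*mods))
            prev = c

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.stem(x)
        feats = []
        for st in self.stages:
            x = st(x)
            feats.append(x)
        return feats


class ConcatFuse(nn.Module):
    """Baseline fusion: channel concatenation + 1x1 projection back to c."""

    def __init__(self, c: int, n_streams: int, rng):
        self.proj = nn.Conv2d(n_streams * c, c, 1, rng=rng)

    def forward(self, *streams: Tensor) -> Tensor:
        return self.proj(nn.concatenate(list(streams), axis=1))


class Neck(nn.Module):
    """Pooling-merge on the deepest scale plus a top-down pathway."""

    def __init__(self, chans, rng):
        c1, c2, c3 = chans
        self.spp = nn.Conv2d(3 * c3, c3, 1, rng=rng)
        self.lat2 = nn.Conv2d(c2 + c3, c2, 3, rng=rng)
        self.lat1 = nn.Conv2d(c1 + c2, c1, 3, rng=rng)

    def forward(self, f1: Tensor, f2: Tensor, f3: Tensor):
        p3 = self.spp(nn.concatenate(
            [f3, nn.max_pool2d(f3, 3), nn.max_pool2d(f3, 5)], axis=1)).silu()
        p2 = self.lat2(nn.concatenate([f2, nn.upsample_nearest(p3, 2)], axis=1)).silu()
        p1 = self.lat1(nn.concatenate([f1, nn.upsample_nearest(p2, 2)], axis=1)).silu()
        return p1, p2, p3


class Head(nn.Module):
    """Per-scale anchor-free prediction head: 4 box + 1 objectness + classes."""

    def __init__(self, c: int, head_ch: int, num_classes: int, rng):
        self.conv = nn.Conv2d(c, head_ch, 3, rng=rng)
        self.out = nn.Conv2d(head_ch, 5 + num_classes, 1, rng=rng)
        # start objectness pessimistic so early training is stable
        self.out.bias.data[4] = -4.0

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.conv(x).silu())


class AuxBranch(nn.Module):
    """RGB auxiliary flow: Silence -> light stages, fed by CBLinear/CBFuse.

    The placeholder (`silence`) passes the raw RGB through untouched; the
    fused deepest pyramid level is linearly split into per-stage channel
    groups (CBLinear), each group is nearest-upsampled to its stage's
    resolution and spliced onto the auxiliary features (CBFuse), and a
    light head yields deep-supervision predictions.  Training only.
    """

    def __init__(self, chans, head_ch: int, num_classes: int, depth: int, rng):
        self.silence = nn.Identity()
        aux_ch = [max(2, c // 2) for c in chans]
        self.stream = Stream(3, aux_ch, depth, rng)
        self.cblinear = nn.Conv2d(chans[2], sum(aux_ch), 1, rng=rng)
        self.aux_ch = aux_ch
        self.cbfuse = [nn.Conv2d(2 * a, a, 1, rng=rng) for a in aux_ch]
        self.heads = [Head(a, head_ch, num_classes, rng) for a in aux_ch]

    def forward(self, rgb: Tensor, fused_deepest: Tensor) -> list[Tensor]:
        feats = self.stream(self.silence(rgb))
        splits = self.cblinear(fused_deepest)
        preds = []
        lo = 0
        for i, (feat, a) in enumerate(zip(feats, self.aux_ch)):
            part = splits[:, lo : lo + a]
            lo += a
            factor = 2 ** (2 - i)  # stride 32 -> stage stride
            if factor > 1:
                part = nn.upsample_nearest(part, factor)
            merged = self.cbfuse[i](nn.concatenate([feat, part], axis=1)).silu()
            preds.append(self.heads[i](merged))
        return preds


class DualStreamDetector(nn.Module):
    """Full detector; ``forward`` returns per-scale raw prediction grids."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        chans = config.effective_channels
        self.streams = [
            Stream(MODALITY_CHANNELS[m], chans, config.stage_depth, rng)
            for m in range(config.modalities)
        ]
        if config.use_lgem:
            self.lgems = [LGEM(c, n_streams=config.modalities, rng=rng) for c in chans]
        else:
            self.lgems = []
        if config.use_rfam:
            fuse_cls = RFAM if config.modalities == 2 else TriRFAM
            self.fusers = [fuse_cls(c, rng=rng) for c in chans]
        else:
            self.fusers = [ConcatFuse(c, config.modalities, rng) for c in chans]
        # the multiplicative fusion weights give the pyramid levels very
        # different dynamic ranges; normalise before the shared neck
        self.fuse_norms = [nn.LayerNorm(c) for c in chans]
        self.neck = Neck(chans, rng)
        self.heads = [Head(c, config.effective_head, config.num_classes, rng)
                      for c in chans]
        self.aux = (AuxBranch(chans, config.effective_head, config.num_classes,
                              config.stage_depth, rng)
                    if config.use_aux else None)

    def forward(self, *inputs: Tensor, with_aux: bool = False):
        if len(inputs) != self.config.modalities:
            raise ValueError(f"expected {self.config.modalities} modality batches, "
                             f"got {len(inputs)}")
        shape0 = inputs[0].shape[2:]
        for i, x in enumerate(inputs[1:], 1):
            if x.shape[2:] != shape0:
                raise ValueError(f"modality size mismatch: {shape0} vs {x.shape[2:]}")
        per_stream = [s(x) for s, x in zip(self.streams, inputs)]
        fused = []
        for i in range(3):
            stage_feats = [ps[i] for ps in per_stream]
            if self.config.use_lgem:
                stage_feats = list(self.lgems[i](*stage_feats))
            fused.append(self.fuse_norms[i](self.fusers[i](*stage_feats)))
        p1, p2, p3 = self.neck(*fused)
        preds = [h(p) for h, p in zip(self.heads, (p1, p2, p3))]
        if with_aux and self.aux is not None:
            return preds, self.aux(inputs[0], fused[2])
        return preds


def build_model(config: ModelConfig, seed: int = 0) -> DualStreamDetector:
    """Construct a detector with seeded, reproducible initial weights."""
    return DualStreamDetector(config, seed=seed)


def count_params(model: nn.Module) -> int:
    """Closed-form parameter count over convolution and FC layers.

    Convolutions contribute ``(K * in + 1) * out`` (K = kernel area; the
    ``+1`` is the bias) and fully connected layers ``(in + 1) * out``.
    Layer-normalisation affine scales/shifts are outside the formula.
    """
    total = 0

    def visit(m):
        nonlocal total
        if isinstance(m, nn.Conv2d):
            cout, cin, kh, kw = m.weight.data.shape
            total += (kh * kw * cin + (1 if m.bias is not None else 0)) * cout
        elif isinstance(m, nn.Linear):
            cin, cout = m.weight.data.shape
            total += (cin + 1) * cout
        for v in vars(m).values():
            if isinstance(v, nn.Module):
                visit(v)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, nn.Module):
                        visit(item)

    visit(model)
    return total


def enumerate_conv_fc_params(model: nn.Module) -> int:
    """Independent oracle: count weight+bias elements of conv/FC layers."""
    total = 0

    def visit(m):
        nonlocal total
        if isinstance(m, (nn.Conv2d, nn.Linear)):
            total += m.weight.data.size
            if getattr(m, "bias", None) is not None:
                total += m.bias.data.size
        for v in vars(m).values():
            if isinstance(v, nn.Module):
                visit(v)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, nn.Module):
                        visit(item)

    visit(model)
    return total


def measure_speed(model: DualStreamDetector, samples: list[tuple[np.ndarray, ...]]) -> float:
    """Mean wall-clock milliseconds per sample (report-only utility)."""
    if not samples:
        raise ValueError("need at least one sample to measure speed")
    t0 = time.perf_counter()
    for arrays in samples:
        model(*[Tensor(a) for a in arrays])
    return (time.perf_counter() - t0) * 1000.0 / len(samples)


def save_checkpoint(model: DualStreamDetector, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.array(json.dumps(asdict(model.config)))
    np.savez(path, **state)


def load_checkpoint(path) -> DualStreamDetector:
    with np.load(path, allow_pickle=False) as z:
        cfg = json.loads(str(z["__config__"]))
        state = {k: z[k] for k in z.files if k != "__config__"}
    for key in ("stage_channels", "input_size"):
        cfg[key] = tuple(cfg[key])
    model = build_model(ModelConfig(**cfg))
    model.load_state_dict(state)
    return model
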