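"""Aligned RGB-D dataset I/O and joint mosaic augmentation.

Labels use the YOLO text dialect: one object per line,
``class x_center y_center width height`` with coordinates normalised to
[0, 1].  Image pairs must be pixel-aligned — the loader rejects RGB/depth
size mismatches up front — and the mosaic augmentation applies the exact
same geometric transform to RGB, depth and labels so alignment survives
augmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image

__all__ = [
    "LabelRecord",
    "ImagePair",
    "read_labels",
    "write_labels",
    "load_pair",
    "save_pair",
    "mosaic4",
    "mosaic_schedule",
]


@dataclass(frozen=True)
class LabelRecord:
    """One object: class id plus a normalised centre/size box."""

    class_id: int
    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError(f"negative class id {self.class_id}")
        for name in ("xc", "yc", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"label field {name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"zero-area box (w={self.w}, h={self.h})")

    def to_xyxy(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Pixel corner coordinates on a width x height canvas."""
        return (
            (self.xc - self.w / 2) * width,
            (self.yc - self.h / 2) * height,
            (self.xc + self.w / 2) * width,
            (self.yc + self.h / 2) * height,
        )


@dataclass
class ImagePair:
    """Pixel-aligned RGB and depth rasters with their shared labels."""

    rgb: np.ndarray            # (h, w, 3) uint8
    depth: np.ndarray          # (h, w) uint8, 0 = invalid-depth sentinel
    labels: list[LabelRecord] = field(default_factory=list)
    ir: np.ndarray | None = None
    source: str | None = None

    def __post_init__(self):
        if self.rgb.shape[:2] != self.depth.shape[:2]:
            raise ValueError(
                f"rgb/depth size mismatch: {self.rgb.shape[:2]} vs {self.depth.shape[:2]}"
            )
        if self.ir is not None and self.ir.shape[:2] != self.rgb.shape[:2]:
            raise ValueError(
                f"ir size mismatch: {self.ir.shape[:2]} vs {self.rgb.shape[:2]}"
            )

    @property
    def size(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


def read_labels(path) -> list[LabelRecord]:
    """Parse a YOLO label file; errors name the offending line."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed number ({e})") from None
            try:
                records.append(LabelRecord(cid, *vals))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return records


def write_labels(records: list[LabelRecord], path) -> None:
    """Write YOLO labels at 6-decimal precision (lossless round trip)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.class_id} {r.xc:.6f} {r.yc:.6f} {r.w:.6f} {r.h:.6f}\n")


def _read_gray(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr


def load_pair(rgb_path, depth_path, label_path=None, ir_path=None) -> ImagePair:
    """Load an aligned pair (plus optional IR); missing labels warn."""
    rgb = iio.imread(rgb_path)
    if rgb.ndim == 2:
        rgb = np.stack([rgb] * 3, axis=-1)
    depth = _read_gray(depth_path)
    ir = _read_gray(ir_path) if ir_path is not None else None
    labels: list[LabelRecord] = []
    if label_path is not None:
        if Path(label_path).exists():
            labels = read_labels(label_path)
        else:
            warnings.warn(f"label file {label_path} missing; using empty label list")
    return ImagePair(rgb=rgb, depth=depth, labels=labels, ir=ir, source=str(rgb_path))


def save_pair(pair: ImagePair, rgb_path, depth_path, label_path=None, ir_path=None) -> None:
    iio.imwrite(rgb_path, pair.rgb)
    iio.imwrite(depth_path, pair.depth)
    if ir_path is not None and pair.ir is not None:
        iio.imwrite(ir_path, pair.ir)
    if label_path is not None:
        write_labels(pair.labels, label_path)


def _resize_rgb(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize for colour content."""
    h, w = out_hw
    return np.asarray(Image.fromarray(img).resize((w, h), Image.BILINEAR))


def _resize_nearest(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize; used for depth/IR so no values are invented
    across object boundaries."""
    h, w = out_hw
    return np.asarray(Image.fromarray(img).resize((w, h), Image.NEAREST))


def mosaic4(pairs: list[ImagePair], out_size: tuple[int, int], seed: int = 0,
            min_area_frac: float = 0.01) -> ImagePair:
    """Stitch four aligned pairs into one canvas with joint label transform.

    A mosaic centre is sampled uniformly within the central half of the
    canvas; each source pair is resized into its quadrant, with the exact
    same geometry applied to RGB (bilinear), depth and IR (nearest) and to
    the label boxes.  Re-normalised boxes are clipped to the unit square
    and boxes whose clipped area falls below ``min_area_frac`` of the
    original are dropped.
    """
    if len(pairs) != 4:
        raise ValueError(f"mosaic needs exactly 4 pairs, got {len(pairs)}")
    H, W = out_size
    rng = np.random.default_rng(seed)
    cy = int(rng.integers(H // 4, 3 * H // 4 + 1))
    cx = int(rng.integers(W // 4, 3 * W // 4 + 1))
    rects = [  # (y0, y1, x0, x1) per quadrant: TL, TR, BL, BR
        (0, cy, 0, cx),
        (0, cy, cx, W),
        (cy, H, 0, cx),
        (cy, H, cx, W),
    ]
    rgb = np.zeros((H, W, 3), dtype=np.uint8)
    depth = np.zeros((H, W), dtype=np.uint8)
    has_ir = all(p.ir is not None for p in pairs)
    ir = np.zeros((H, W), dtype=np.uint8) if has_ir else None
    labels: list[LabelRecord] = []
    for pair, (y0, y1, x0, x1) in zip(pairs, rects):
        qh, qw = y1 - y0, x1 - x0
        if qh <= 0 or qw <= 0:
            continue
        rgb[y0:y1, x0:x1] = _resize_rgb(pair.rgb, (qh, qw))
        depth[y0:y1, x0:x1] = _resize_nearest(pair.depth, (qh, qw))
        if has_ir:
            ir[y0:y1, x0:x1] = _resize_nearest(pair.ir, (qh, qw))
        for rec in pair.labels:
            # source-normalised -> canvas-normalised
            xc = (x0 + rec.xc * qw) / W
            yc = (y0 + rec.yc * qh) / H
            bw = rec.w * qw / W
            bh = rec.h * qh / H
            lo_x, hi_x = np.clip([xc - bw / 2, xc + bw / 2], 0.0, 1.0)
            lo_y, hi_y = np.clip([yc - bh / 2, yc + bh / 2], 0.0, 1.0)
            cw, ch = hi_x - lo_x, hi_y - lo_y
            if cw <= 0 or ch <= 0 or cw * ch < min_area_frac * bw * bh:
                continue
            labels.append(LabelRecord(rec.class_id, (lo_x + hi_x) / 2,
                                      (lo_y + hi_y) / 2, cw, ch))
    return ImagePair(rgb=rgb, depth=depth, labels=labels, ir=ir, source="mosaic")


def mosaic_schedule(epoch: int, total_epochs: int, close_window: int = 30) -> bool:
    """True while mosaic augmentation is active.

    The augmentation is switched off for the final ``close_window`` epochs
    (default 30), which sharpens convergence at the end of training.
    """
    if not (0 <= epoch < total_epochs):
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    return epoch < total_epochs - close_window


def clip_label(rec: LabelRecord) -> LabelRecord | None:
    """Clip a label to the unit square; None if nothing remains."""
    lo_x = max(rec.xc - rec.w / 2, 0.0)
    hi_x = min(rec.xc + rec.w / 2, 1.0)
    lo_y = max(rec.yc - rec.h / 2, 0.0)
    hi_y = min(rec.yc + rec.h / 2, 1.0)
    if hi_x <= lo_x or hi_y <= lo_y:
        return None
    return replace(rec, xc=(lo_x + hi_x) / 2, yc=(lo_y + hi_y) / 2,
                   w=hi_x - lo_x, h=hi_y - lo_y)
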