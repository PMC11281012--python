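"""Synthetic aligned RGB-D orchard scenes with YOLO labels.

The generator fabricates the statistical structure of a young-peach
detection dataset so the whole pipeline is testable without any download:

* elliptical "fruits" biased toward the image centre with small boxes;
* four occlusion classes — 0 False (unshaded), 1 Leaf, 2 Branch,
  3 Fruit — drawn with class-dependent occluders (leaf blobs, branch
  strokes, an overlapping unlabelled fruit), with a Leaf-heavy default
  mix mirroring the imbalance typical of orchard canopies;
* a depth raster encoding per-object distance (nearer = smaller value)
  with additive noise, where 0 is the invalid-depth sentinel;
* the characteristic failure modes of consumer RGB-D rigs: dark/glare
  lighting corruption of the RGB channel (depth untouched) and annular
  depth voids at fruit boundaries.

Everything is deterministic under the configured seed, and datasets are
written with a manifest from which they regenerate bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset_io import ImagePair, LabelRecord, save_pair

__all__ = [
    "CLASS_NAMES",
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "corrupt_lighting",
    "carve_depth_voids",
    "generate_dataset",
    "regenerate_from_manifest",
    "easy_config",
]

CLASS_NAMES = ("False", "Leaf", "Branch", "Fruit")

#: Leaf-heavy default mix: most canopy fruits are leaf-shaded.
_DEFAULT_MIX = (0.25, 0.45, 0.15, 0.15)


@dataclass(frozen=True)
class SceneConfig:
    """Conditions under which scenes are fabricated.

    ``fruit_radius_range`` is in pixels; fruits are placed with a
    centre-biased Gaussian so the targets cluster in the central region.
    ``depth_void_rate`` is the per-pixel probability of carving an
    invalid-depth hole on a fruit's boundary annulus.
    """

    image_size: tuple[int, int] = (128, 128)
    n_fruit_range: tuple[int, int] = (2, 5)
    class_mix: tuple[float, float, float, float] = _DEFAULT_MIX
    lighting: str = "normal"          # normal | dark | glare
    depth_void_rate: float = 0.3
    fruit_radius_range: tuple[int, int] = (8, 16)
    with_ir: bool = False
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError(f"zero-area image size {self.image_size}")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class mix must sum to 1, got {self.class_mix}")
        if self.lighting not in ("normal", "dark", "glare"):
            raise ValueError(f"unknown lighting mode {self.lighting!r}")
        if not (0.0 <= self.depth_void_rate <= 1.0):
            raise ValueError(f"depth_void_rate {self.depth_void_rate} outside [0, 1]")


@dataclass
class SyntheticScene:
    rgb: np.ndarray
    depth: np.ndarray
    labels: list[LabelRecord]
    config: SceneConfig
    ir: np.ndarray | None = None

    def as_pair(self) -> ImagePair:
        return ImagePair(rgb=self.rgb, depth=self.depth, labels=list(self.labels),
                         ir=self.ir, source=f"synthetic:{self.config.seed}")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _draw_leaf(rgb, rng, cy, cx, r):
    h, w = rgb.shape[:2]
    ly = cy + rng.uniform(-0.7, 0.2) * r
    lx = cx + rng.uniform(-0.8, 0.8) * r
    mask = _ellipse_mask(h, w, ly, lx, r * rng.uniform(0.5, 0.9), r * rng.uniform(0.7, 1.2))
    colour = np.array([30 + rng.integers(0, 30), 110 + rng.integers(0, 60),
                       30 + rng.integers(0, 25)], dtype=np.uint8)
    rgb[mask] = colour
    return mask


def _draw_branch(rgb, rng, cy, cx, r, h, w):
    angle = rng.uniform(0, np.pi)
    thickness = max(2, int(r * rng.uniform(0.25, 0.45)))
    yy, xx = np.mgrid[0:h, 0:w]
    # distance from the line through (cy, cx) at `angle`
    d = np.abs(-(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle))
    near = np.abs((xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)) < r * 1.8
    mask = (d < thickness) & near
    colour = np.array([90 + rng.integers(0, 30), 60 + rng.integers(0, 20),
                       30 + rng.integers(0, 15)], dtype=np.uint8)
    rgb[mask] = colour
    return mask


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one aligned RGB-D scene with labels, deterministically."""
    h, w = config.image_size
    rng = np.random.default_rng(config.seed)
    # foliage-like background
    base = rng.integers(25, 60, size=(h, w), dtype=np.uint8)
    rgb = np.stack([base // 2, base + 40, base // 2 + 10], axis=-1).astype(np.uint8)
    depth = np.full((h, w), 220, dtype=np.uint8)  # background is far
    depth = (depth + rng.integers(-10, 10, size=(h, w))).clip(1, 255).astype(np.uint8)

    n_lo, n_hi = config.n_fruit_range
    n_fruit = int(rng.integers(n_lo, n_hi + 1))
    labels: list[LabelRecord] = []
    for _ in range(n_fruit):
        r = float(rng.uniform(*config.fruit_radius_range))
        # centre-biased placement, clamped so the box stays inside
        cy = float(np.clip(rng.normal(h / 2, h / 5), r + 1, h - r - 2))
        cx = float(np.clip(rng.normal(w / 2, w / 5), r + 1, w - r - 2))
        ry, rx = r * rng.uniform(0.85, 1.1), r
        cls = int(rng.choice(4, p=config.class_mix))
        fruit_mask = _ellipse_mask(h, w, cy, cx, ry, rx)
        peach = np.array([220 + rng.integers(0, 30), 120 + rng.integers(0, 50),
                          90 + rng.integers(0, 40)], dtype=np.uint8)
        rgb[fruit_mask] = peach
        # per-object distance, nearer than background
        dist = int(rng.integers(60, 140))
        depth[fruit_mask] = np.clip(
            dist + rng.integers(-5, 5, size=int(fruit_mask.sum())), 1, 255
        ).astype(np.uint8)
        if cls == 1:
            occ = _draw_leaf(rgb, rng, cy, cx, r)
            depth[occ] = np.clip(dist - rng.integers(10, 30), 1, 255)
        elif cls == 2:
            occ = _draw_branch(rgb, rng, cy, cx, r, h, w)
            depth[occ] = np.clip(dist - rng.integers(10, 30), 1, 255)
        elif cls == 3:
            oy = cy + rng.uniform(0.5, 0.9) * r * rng.choice([-1, 1])
            ox = cx + rng.uniform(0.5, 0.9) * r * rng.choice([-1, 1])
            occ = _ellipse_mask(h, w, oy, ox, r * 0.9, r * 0.9)
            rgb[occ] = np.clip(peach.astype(int) - 25, 0, 255).astype(np.uint8)
            depth[occ] = np.clip(dist - rng.integers(5, 20), 1, 255)
        # label covers the full (possibly occluded) fruit extent
        bw, bh = 2 * rx / w, 2 * ry / h
        labels.append(LabelRecord(cls, np.clip(cx / w, 0, 1), np.clip(cy / h, 0, 1),
                                  min(bw, 1.0), min(bh, 1.0)))

    if config.lighting != "normal":
        rgb = corrupt_lighting(rgb, config.lighting, seed=config.seed + 1)
    if config.depth_void_rate > 0:
        depth = carve_depth_voids(depth, labels, config.depth_void_rate,
                                  seed=config.seed + 2)
    ir = None
    if config.with_ir:
        # fruit thermal emission is negligible: IR is a near-constant,
        # low-information raster
        ir = np.full((h, w), 120, dtype=np.uint8)
        ir = (ir + rng.integers(-3, 4, size=(h, w))).astype(np.uint8)
    return SyntheticScene(rgb=rgb, depth=depth, labels=labels, config=config, ir=ir)


def corrupt_lighting(rgb: np.ndarray, mode: str, seed: int = 0,
                     gain: float = 0.35, noise_std: float = 8.0) -> np.ndarray:
    """Simulate uncontrolled lighting on the RGB channel only.

    ``dark``: global gain < 1 plus sensor noise; ``glare``: a saturated
    bright patch overwrites local content.  Depth is never touched — it is
    the modality robust to lighting.
    """
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected a 3-channel raster, got shape {rgb.shape}")
    rng = np.random.default_rng(seed)
    h, w = rgb.shape[:2]
    if mode == "dark":
        out = rgb.astype(np.float64) * gain
        if noise_std > 0:
            out += rng.normal(0, noise_std, rgb.shape)
        return out.clip(0, 255).astype(np.uint8)
    if mode == "glare":
        out = rgb.copy()
        r = max(3, int(min(h, w) * rng.uniform(0.15, 0.3)))
        cy = int(rng.integers(r, h - r)) if h > 2 * r else h // 2
        cx = int(rng.integers(r, w - r)) if w > 2 * r else w // 2
        mask = _ellipse_mask(h, w, cy, cx, r, r)
        out[mask] = 255
        halo = _ellipse_mask(h, w, cy, cx, r * 1.5, r * 1.5) & ~mask
        out[halo] = np.clip(out[halo].astype(int) + 90, 0, 255).astype(np.uint8)
        return out
    raise ValueError(f"unknown lighting mode {mode!r}")


def carve_depth_voids(depth: np.ndarray, labels: list[LabelRecord],
                      rate: float, seed: int = 0) -> np.ndarray:
    """Set boundary-annulus pixels of each labelled fruit to the 0 sentinel.

    Consumer depth sensors lose returns at object silhouettes; the void is
    carved with per-pixel probability ``rate`` on the annulus between 80%
    and 110% of each label's elliptical extent.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate {rate} outside [0, 1]")
    if rate == 0 or not labels:
        return depth.copy()
    rng = np.random.default_rng(seed)
    out = depth.copy()
    h, w = depth.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    for rec in labels:
        cy, cx = rec.yc * h, rec.xc * w
        ry, rx = max(rec.h * h / 2, 1e-6), max(rec.w * w / 2, 1e-6)
        rho = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        annulus = (rho >= 0.8 ** 2) & (rho <= 1.1 ** 2)
        hit = annulus & (rng.random((h, w)) < rate)
        out[hit] = 0
    return out


def _split_counts(n: int) -> tuple[int, int, int]:
    if n < 10:
        raise ValueError(f"need at least 10 scenes for an 8:1:1 split, got {n}")
    n_train = (n * 8) // 10
    n_val = n // 10
    return n_train, n_val, n - n_train - n_val


def _scene_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 1_000_003 + index) % (2 ** 31))


def generate_dataset(n: int, config: SceneConfig, out_dir,
                     split: tuple[int, int, int] = (8, 1, 1)) -> dict:
    """Write ``n`` scenes in an 8:1:1 train/val/test layout with a manifest.

    Layout: ``images/{split}/scene_%05d_{rgb,depth}.png`` and
    ``labels/{split}/scene_%05d.txt``.  The manifest records the config
    and every per-scene seed, so :func:`regenerate_from_manifest`
    reproduces the dataset bit-exactly.
    """
    if tuple(split) != (8, 1, 1):
        raise ValueError(f"only the 8:1:1 split is supported, got {split}")
    out_dir = Path(out_dir)
    n_train, n_val, n_test = _split_counts(n)
    assignment = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    manifest = {
        "n": n,
        "split_counts": {"train": n_train, "val": n_val, "test": n_test},
        "config": {**asdict(config)},
        "depth_sentinel": 0,
        "class_names": list(CLASS_NAMES),
        "scenes": [],
    }
    for sub in ("train", "val", "test"):
        (out_dir / "images" / sub).mkdir(parents=True, exist_ok=True)
        (out_dir / "labels" / sub).mkdir(parents=True, exist_ok=True)
    for i, sub in enumerate(assignment):
        seed_i = _scene_seed(config.seed, i)
        scene = generate_scene(
            SceneConfig(**{**asdict(config), "seed": seed_i})
        )
        stem = f"scene_{i:05d}"
        rgb_p = out_dir / "images" / sub / f"{stem}_rgb.png"
        depth_p = out_dir / "images" / sub / f"{stem}_depth.png"
        label_p = out_dir / "labels" / sub / f"{stem}.txt"
        ir_p = out_dir / "images" / sub / f"{stem}_ir.png" if config.with_ir else None
        save_pair(scene.as_pair(), rgb_p, depth_p, label_p, ir_p)
        manifest["scenes"].append({"index": i, "split": sub, "seed": seed_i,
                                   "stem": stem})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def regenerate_from_manifest(manifest: dict, out_dir) -> dict:
    """Re-create a dataset from its manifest (bit-exact by construction)."""
    cfg = manifest["config"]
    config = SceneConfig(**{**cfg,
                            "image_size": tuple(cfg["image_size"]),
                            "n_fruit_range": tuple(cfg["n_fruit_range"]),
                            "class_mix": tuple(cfg["class_mix"]),
                            "fruit_radius_range": tuple(cfg["fruit_radius_range"])})
    return generate_dataset(manifest["n"], config, out_dir)


def easy_config(seed: int = 0, image_size: tuple[int, int] = (128, 128)) -> SceneConfig:
    """Easy study conditions: large unoccluded fruits, clean modalities.

    Used for the desk-scale end-to-end training sanity check: all fruits
    unshaded (class 0), normal lighting, no depth voids.
    """
    return SceneConfig(
        image_size=image_size,
        n_fruit_range=(1, 3),
        class_mix=(1.0, 0.0, 0.0, 0.0),
        lighting="normal",
        depth_void_rate=0.0,
        fruit_radius_range=(14, 20),
        seed=seed,
    )
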