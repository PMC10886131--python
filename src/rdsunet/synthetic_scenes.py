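"""Synthetic corn/weed field scenes.

The generator emulates the statistical structure of early-season maize
field imagery for segmentation experiments: a textured soil background,
one to a few large multi-lobed green corn seedlings, a variable number of
much smaller green weeds (round blobs and thin blades), deliberate
overlap/occlusion between the two foreground classes, and global
illumination variation. Shapes are parametric (unions of rotated ellipses
and discs) rather than photorealistic: this keeps every painted pixel
exactly checkable while still exercising segmentation of scale-disparate,
color-overlapping classes.

Occlusion is resolved by paint order: corn plants are drawn first, weeds
afterwards, and a weed placed over a corn plant overwrites its pixels in
both image and mask, so image and mask stay paint-order consistent.

The two green hue distributions overlap but differ in mean, so class
identity is carried mostly by shape and scale, not color alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .errors import SpecificationError
from .scene import BACKGROUND, CORN, WEED, LabeledScene

Range = Tuple[float, float]


@dataclass(frozen=True)
class SceneSpec:
    """Statistical parameters of one synthetic field scene.

    Counts and scales are inclusive uniform ranges sampled per scene.
    """

    image_size: int = 224
    n_corn: Tuple[int, int] = (1, 3)
    n_weeds: Tuple[int, int] = (0, 20)
    corn_scale: Range = (30.0, 60.0)        # characteristic corn radius, px
    weed_scale: Range = (3.0, 12.0)         # characteristic weed radius, px
    corn_lobes: Tuple[int, int] = (3, 6)    # (0, 0) renders corn as a disc
    overlap_fraction: float = 0.2           # P(weed placed over a corn plant)
    illumination: Range = (0.7, 1.3)        # multiplicative brightness
    background_texture: float = 12.0        # soil-noise amplitude, 8-bit units
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise SpecificationError(
                f"image_size must be >= 32, got {self.image_size}")
        for name in ("n_corn", "n_weeds", "corn_scale", "weed_scale",
                     "corn_lobes", "illumination"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SpecificationError(f"{name}: range low {lo} > high {hi}")
            if lo < 0:
                raise SpecificationError(f"{name}: negative values not allowed")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise SpecificationError(
                f"overlap_fraction must be in [0, 1], got {self.overlap_fraction}")
        if self.background_texture < 0:
            raise SpecificationError("background_texture must be >= 0")


# ---------------------------------------------------------------------------
# shape rasterization (vectorized analytic footprints)
# ---------------------------------------------------------------------------

def _disc_footprint(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _ellipse_footprint(size: int, cy: float, cx: float, a: float, b: float,
                       theta: float) -> np.ndarray:
    """Rotated ellipse with semi-axes a (along theta) and b."""
    yy, xx = np.ogrid[:size, :size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _paint(image: np.ndarray, mask: np.ndarray, footprint: np.ndarray,
           color: np.ndarray, cls: int, rng: np.random.Generator) -> None:
    """Paint a footprint with slight per-pixel color texture; later paints
    overwrite earlier ones (occlusion by paint order)."""
    n = int(footprint.sum())
    if n == 0:
        return
    jitter = rng.normal(0.0, 6.0, size=(n, 3))
    image[footprint] = np.clip(color[None] + jitter, 0, 255)
    mask[footprint] = cls


def _corn_footprint(size: int, cy: float, cx: float, r: float, lobes: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Multi-lobed elongated rosette; lobes == 0 degenerates to a disc."""
    if lobes == 0:
        return _disc_footprint(size, cy, cx, r)
    fp = _disc_footprint(size, cy, cx, 0.35 * r)
    base = rng.uniform(0, 2 * np.pi)
    for i in range(lobes):
        theta = base + 2 * np.pi * i / lobes + rng.normal(0, 0.15)
        length = r * rng.uniform(0.8, 1.05)
        width = r * rng.uniform(0.16, 0.26)
        off = 0.5 * length
        fp |= _ellipse_footprint(size, cy + off * np.sin(theta),
                                 cx + off * np.cos(theta),
                                 length * 0.55, width, theta)
    return fp


def _weed_footprint(size: int, cy: float, cx: float, s: float,
                    rng: np.random.Generator) -> np.ndarray:
    if rng.random() < 0.5:  # round blob
        return _disc_footprint(size, cy, cx, s)
    # thin blade
    theta = rng.uniform(0, np.pi)
    return _ellipse_footprint(size, cy, cx, s * rng.uniform(2.0, 3.5),
                              max(0.8, 0.25 * s), theta)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _soil_background(size: int, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    base = np.array([118.0, 86.0, 60.0]) + rng.normal(0, 8.0, 3)
    img = np.tile(base, (size, size, 1))
    if amplitude > 0:
        coarse = rng.normal(0, amplitude, (max(size // 8, 1),) * 2)
        coarse = zoom(coarse, size / coarse.shape[0], order=1)[:size, :size]
        img += gaussian_filter(coarse, 1.0)[..., None]
        img += rng.normal(0, 0.35 * amplitude, (size, size, 3))
    return img


def generate_scene(spec: SceneSpec, seed: int) -> LabeledScene:
    """Render one labeled scene; bit-identical for identical (spec, seed)."""
    rng = np.random.default_rng(seed)
    size = spec.image_size
    img = _soil_background(size, spec.background_texture, rng)
    mask = np.zeros((size, size), np.uint8)

    n_corn = int(rng.integers(spec.n_corn[0], spec.n_corn[1] + 1))
    n_weeds = int(rng.integers(spec.n_weeds[0], spec.n_weeds[1] + 1))

    corn_circles = []
    for _ in range(n_corn):
        r = rng.uniform(*spec.corn_scale)
        margin = min(r, size / 2 - 1)
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        lobes = int(rng.integers(spec.corn_lobes[0], spec.corn_lobes[1] + 1))
        fp = _corn_footprint(size, cy, cx, r, lobes, rng)
        color = np.array([45.0, 132.0, 52.0]) + rng.normal(0, 14.0, 3)
        _paint(img, mask, fp, color, CORN, rng)
        corn_circles.append((cy, cx, r))

    for _ in range(n_weeds):
        s = rng.uniform(*spec.weed_scale)
        if corn_circles and rng.random() < spec.overlap_fraction:
            cy0, cx0, r0 = corn_circles[int(rng.integers(len(corn_circles)))]
            ang = rng.uniform(0, 2 * np.pi)
            rad = r0 * np.sqrt(rng.random())
            cy = float(np.clip(cy0 + rad * np.sin(ang), 0, size - 1))
            cx = float(np.clip(cx0 + rad * np.cos(ang), 0, size - 1))
        else:
            cy = rng.uniform(0, size - 1)
            cx = rng.uniform(0, size - 1)
        fp = _weed_footprint(size, cy, cx, s, rng)
        color = np.array([80.0, 148.0, 62.0]) + rng.normal(0, 16.0, 3)
        _paint(img, mask, fp, color, WEED, rng)

    illum = rng.uniform(*spec.illumination)
    img = np.clip(img * illum, 0, 255).astype(np.uint8)
    return LabeledScene(image=img, mask=mask)


def generate_dataset(spec: SceneSpec, n: int, out_dir,
                     seed: Optional[int] = None):
    """Write ``n`` scenes in Pascal-VOC segmentation layout.

    Sample ids are sequential zero-padded integers; all ids initially go to
    the ``train`` split list (``split_dataset`` repartitions later).
    Returns the :class:`~rdsunet.vocdata.DatasetIndex` of written samples.
    """
    from .vocdata import DatasetIndex, write_sample

    if n < 1:
        raise SpecificationError(f"dataset size must be >= 1, got {n}")
    base_seed = spec.seed if seed is None else seed
    out_dir = Path(out_dir)
    index = DatasetIndex.create(out_dir)
    for i in range(n):
        sid = f"{i:05d}"
        scene_seed = int(np.random.SeedSequence((base_seed, i))
                         .generate_state(1)[0] % (2 ** 31))
        scene = generate_scene(spec, scene_seed)
        write_sample(index, sid, scene)
        index.add(sid, split="train")
    index.write_split_files()
    return index
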