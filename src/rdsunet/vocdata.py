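"""Pascal-VOC segmentation dataset I/O, Labelme conversion, augmentation.

Layout::

    <root>/JPEGImages/<id>.jpg            8-bit RGB
    <root>/SegmentationClass/<id>.png     indexed-palette PNG, indices 0..2
    <root>/ImageSets/Segmentation/{train,val,test}.txt   one id per line

The augmentation protocol applies four strategies, each independently with
probability ``p_apply`` (default 0.5): additive Gaussian noise, random
rotation (identical geometric transform on image and mask, nearest-neighbor
for the mask so labels never interpolate), a photometric
brightness/contrast/histogram adjustment, and motion blur. Only rotation
touches the mask; the photometric strategies perturb the image alone.

Dataset expansion keeps the originals and appends augmented replicates,
round-robin over source images, until the configured target count is
reached (the reference protocol expands 500 scenes to 4000). Splitting into
train/val/test shuffles at the level of source groups — all replicates of
one source land in the same split — so augmented copies can never leak
across the train/test boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from scipy.ndimage import convolve, map_coordinates

from .errors import DataIOError, FormatError, SpecificationError
from .scene import BACKGROUND, N_CLASSES, PALETTE, LabeledScene

SPLITS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------

@dataclass
class DatasetIndex:
    """Ordered ids of a VOC-layout dataset plus split assignment and
    augmentation provenance (augmented id -> source id)."""

    root: Path
    ids: List[str] = field(default_factory=list)
    split_of: Dict[str, str] = field(default_factory=dict)
    source_of: Dict[str, str] = field(default_factory=dict)

    # -- paths -----------------------------------------------------------
    def image_path(self, sid: str) -> Path:
        return self.root / "JPEGImages" / f"{sid}.jpg"

    def mask_path(self, sid: str) -> Path:
        return self.root / "SegmentationClass" / f"{sid}.png"

    def split_file(self, split: str) -> Path:
        return self.root / "ImageSets" / "Segmentation" / f"{split}.txt"

    # -- construction ----------------------------------------------------
    @classmethod
    def create(cls, root) -> "DatasetIndex":
        root = Path(root)
        try:
            (root / "JPEGImages").mkdir(parents=True, exist_ok=True)
            (root / "SegmentationClass").mkdir(parents=True, exist_ok=True)
            (root / "ImageSets" / "Segmentation").mkdir(parents=True,
                                                        exist_ok=True)
        except OSError as e:
            raise DataIOError(f"cannot create dataset at {root}: {e}") from e
        return cls(root=root)

    @classmethod
    def from_directory(cls, root) -> "DatasetIndex":
        root = Path(root)
        if not root.is_dir():
            raise DataIOError(f"dataset directory not found: {root}")
        idx = cls(root=root)
        for split in SPLITS:
            f = idx.split_file(split)
            if f.is_file():
                for line in f.read_text().splitlines():
                    sid = line.strip()
                    if sid:
                        idx.add(sid, split=split)
        if not idx.ids:
            raise DataIOError(f"no split lists found under {root}")
        return idx

    def add(self, sid: str, split: str = "train",
            source: Optional[str] = None) -> None:
        if split not in SPLITS:
            raise SpecificationError(f"unknown split {split!r}")
        if sid not in self.split_of:
            self.ids.append(sid)
        self.split_of[sid] = split
        self.source_of[sid] = source if source is not None else sid

    def split_ids(self, split: str) -> List[str]:
        return [i for i in self.ids if self.split_of[i] == split]

    def write_split_files(self) -> None:
        for split in SPLITS:
            ids = self.split_ids(split)
            self.split_file(split).write_text(
                "".join(f"{i}\n" for i in ids))

    def validate_files(self) -> None:
        for sid in self.ids:
            if not self.image_path(sid).is_file():
                raise DataIOError(f"missing image for id {sid}")
            if not self.mask_path(sid).is_file():
                raise DataIOError(f"missing mask for id {sid}")

    def __len__(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# sample I/O
# ---------------------------------------------------------------------------

def write_mask_png(path, mask: np.ndarray) -> None:
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(PALETTE)
    im.save(path, format="PNG")


def read_mask_png(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("P") if im.mode != "P" else im)
    if arr.max(initial=0) >= N_CLASSES:
        raise FormatError(
            f"mask {path} contains index {int(arr.max())}; "
            f"allowed 0..{N_CLASSES - 1}")
    return arr.astype(np.uint8)


def write_sample(index: DatasetIndex, sid: str, scene: LabeledScene) -> None:
    try:
        Image.fromarray(scene.image).save(index.image_path(sid),
                                          format="JPEG", quality=95)
        write_mask_png(index.mask_path(sid), scene.mask)
    except OSError as e:
        raise DataIOError(f"cannot write sample {sid}: {e}") from e


def load_sample(index: DatasetIndex, sid: str,
                target_size: Optional[int] = 224) -> LabeledScene:
    """Load one sample; resize to ``target_size`` square if it differs
    (image: bilinear, mask: nearest-neighbor). ``target_size=None`` keeps
    the stored resolution."""
    if sid not in index.split_of:
        raise DataIOError(f"id {sid!r} not in dataset index")
    img_p, mask_p = index.image_path(sid), index.mask_path(sid)
    if not img_p.is_file():
        raise DataIOError(f"missing image file {img_p}")
    if not mask_p.is_file():
        raise DataIOError(f"missing mask file {mask_p}")
    with Image.open(img_p) as im:
        im = im.convert("RGB")
        if target_size is not None and im.size != (target_size, target_size):
            im = im.resize((target_size, target_size), Image.BILINEAR)
        image = np.asarray(im)
    mask = read_mask_png(mask_p)
    if target_size is not None and mask.shape != (target_size, target_size):
        mask = np.asarray(Image.fromarray(mask).resize(
            (target_size, target_size), Image.NEAREST))
    return LabeledScene(image=image, mask=mask)


# ---------------------------------------------------------------------------
# Labelme conversion
# ---------------------------------------------------------------------------

def labelme_to_voc(json_path, class_names: Sequence[str] = ("corn", "grass"),
                   ) -> LabeledScene:
    """Convert a Labelme polygon annotation to a class-index mask.

    ``class_names`` maps labels to indices 1..len(class_names) in order
    (the default maps "corn" -> 1 and "grass" -> 2, the weed class).
    Polygons are rasterized in file order, later polygons overwriting
    earlier ones; a pixel belongs to a polygon when its center lies inside.
    """
    json_path = Path(json_path)
    if not json_path.is_file():
        raise DataIOError(f"annotation file not found: {json_path}")
    data = json.loads(json_path.read_text())
    h = int(data["imageHeight"])
    w = int(data["imageWidth"])
    mask = np.zeros((h, w), np.uint8)
    label_to_idx = {name: i + 1 for i, name in enumerate(class_names)}
    yy, xx = np.mgrid[:h, :w]
    centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    for shape in data.get("shapes", []):
        label = shape.get("label", "")
        if label not in label_to_idx:
            raise FormatError(
                f"unknown label {label!r}; expected one of "
                f"{sorted(label_to_idx)}")
        pts = np.asarray(shape["points"], dtype=float)
        inside = MplPath(pts).contains_points(centers).reshape(h, w)
        mask[inside] = label_to_idx[label]
    image = np.zeros((h, w, 3), np.uint8)
    if data.get("imageData"):
        import base64
        import io
        with Image.open(io.BytesIO(base64.b64decode(data["imageData"]))) as im:
            image = np.asarray(im.convert("RGB"))
    return LabeledScene(image=image, mask=mask)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationConfig:
    p_apply: float = 0.5
    noise_sigma: float = 8.0                 # 8-bit intensity units
    rotation_range: float = 30.0             # degrees, uniform in +-range
    brightness_range: Tuple[float, float] = (0.8, 1.2)
    contrast_range: Tuple[float, float] = (0.8, 1.2)
    equalize_histogram: bool = True
    motion_blur_len: int = 7                 # kernel length, px
    target_count: int = 4000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise SpecificationError(
                f"p_apply must be in [0, 1], got {self.p_apply}")
        if self.noise_sigma < 0 or self.rotation_range < 0:
            raise SpecificationError("noise_sigma/rotation_range must be >= 0")
        for name in ("brightness_range", "contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise SpecificationError(f"invalid {name}: ({lo}, {hi})")
        if self.motion_blur_len < 1:
            raise SpecificationError("motion_blur_len must be >= 1")


def _rotate_pair(image: np.ndarray, mask: np.ndarray, angle_deg: float
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Rotate image (bilinear) and mask (nearest) by the same angle about
    the array center ((N-1)/2); border: per-image median background color
    for the image, class 0 for the mask."""
    h, w = mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    yy, xx = np.mgrid[:h, :w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    # inverse map: rotate output coords by -angle to find source coords
    src_y = cy + ct * dy + st * dx
    src_x = cx - st * dy + ct * dx
    bg = mask == BACKGROUND
    fill = (np.median(image[bg].reshape(-1, 3), axis=0)
            if bg.any() else np.zeros(3))
    out_img = np.empty_like(image)
    for c in range(3):
        out_img[..., c] = map_coordinates(
            image[..., c].astype(np.float64), [src_y, src_x],
            order=1, cval=float(fill[c]), mode="constant").round().clip(0, 255)
    out_mask = map_coordinates(mask, [src_y, src_x], order=0,
                               cval=BACKGROUND, mode="constant")
    return out_img.astype(np.uint8), out_mask.astype(np.uint8)


def _equalize_luminance(img: np.ndarray) -> np.ndarray:
    lum = (0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2])
    hist, _ = np.histogram(lum, bins=256, range=(0, 256))
    cdf = hist.cumsum().astype(np.float64)
    if cdf[-1] == 0:
        return img
    cdf = cdf / cdf[-1] * 255.0
    lum_eq = np.interp(lum, np.arange(256), cdf)
    scale = (lum_eq + 1.0) / (lum + 1.0)
    return np.clip(img * scale[..., None], 0, 255)


def _motion_blur_kernel(length: int, angle_rad: float) -> np.ndarray:
    k = np.zeros((length, length))
    c = (length - 1) / 2.0
    ts = np.linspace(-c, c, 4 * length)
    rr = np.round(c + ts * np.sin(angle_rad)).astype(int)
    cc = np.round(c + ts * np.cos(angle_rad)).astype(int)
    k[rr.clip(0, length - 1), cc.clip(0, length - 1)] = 1.0
    return k / k.sum()


def augment(scene: LabeledScene, config: AugmentationConfig,
            seed: int) -> LabeledScene:
    """Apply the four-strategy protocol, each with probability p_apply."""
    rng = np.random.default_rng(seed)
    img = scene.image.astype(np.float64)
    mask = scene.mask.copy()

    # draw all application coins up-front so the random stream is stable
    apply = rng.random(4) < config.p_apply

    if apply[0] and config.noise_sigma > 0:        # Gaussian noise
        img = np.clip(img + rng.normal(0, config.noise_sigma, img.shape),
                      0, 255)
    if apply[1] and config.rotation_range > 0:     # random rotation
        angle = rng.uniform(-config.rotation_range, config.rotation_range)
        img_u8, mask = _rotate_pair(
            np.clip(img, 0, 255).astype(np.uint8), mask, angle)
        img = img_u8.astype(np.float64)
    if apply[2]:                                   # brightness/contrast/hist
        b = rng.uniform(*config.brightness_range)
        c = rng.uniform(*config.contrast_range)
        img = np.clip(img * b, 0, 255)
        img = np.clip((img - img.mean()) * c + img.mean(), 0, 255)
        if config.equalize_histogram:
            img = _equalize_luminance(img)
    if apply[3] and config.motion_blur_len > 1:    # motion blur
        kern = _motion_blur_kernel(config.motion_blur_len,
                                   rng.uniform(0, np.pi))
        for ch in range(3):
            img[..., ch] = convolve(img[..., ch], kern, mode="nearest")
        img = np.clip(img, 0, 255)

    return LabeledScene(image=np.round(img).astype(np.uint8), mask=mask)


# ---------------------------------------------------------------------------
# expansion and splitting
# ---------------------------------------------------------------------------

def expand_dataset(index: DatasetIndex,
                   config: AugmentationConfig) -> DatasetIndex:
    """Augment in place until the dataset holds ``target_count`` samples.

    Originals are retained; replicate k of the expansion round-robins over
    source ids, and augmented ids record provenance as ``<src>_aug<n>``.
    Deterministic for a fixed config seed.
    """
    n = len(index.ids)
    if n == 0:
        raise SpecificationError("cannot expand an empty dataset")
    if config.target_count < n:
        raise SpecificationError(
            f"target_count {config.target_count} < current count {n}")
    sources = list(index.ids)
    for k in range(config.target_count - n):
        src = sources[k % n]
        rep = k // n + 1
        sid = f"{src}_aug{rep}"
        scene = load_sample(index, src, target_size=None)
        aug_seed = int(np.random.SeedSequence((config.seed, k))
                       .generate_state(1)[0] % (2 ** 31))
        write_sample(index, sid, augment(scene, config, aug_seed))
        index.add(sid, split=index.split_of[src], source=src)
    index.write_split_files()
    return index


def split_dataset(index: DatasetIndex, test_fraction: float,
                  val_fraction: float, seed: int) -> DatasetIndex:
    """Partition into train/val/test (e.g. 0.2/0.2 -> 64/16/20 percent).

    The shuffle operates on source groups, so every augmented replicate
    follows its source into the same split. Target sizes are
    round(N * test_fraction) for test, then round(M * val_fraction) of the
    M remaining for val; with equally sized groups (the expansion protocol
    guarantees this when counts divide evenly) the partition is exact.
    """
    for name, f in (("test_fraction", test_fraction),
                    ("val_fraction", val_fraction)):
        if not 0.0 < f < 1.0:
            raise SpecificationError(f"{name} must be in (0, 1), got {f}")
    groups: Dict[str, List[str]] = {}
    for sid in index.ids:
        groups.setdefault(index.source_of.get(sid, sid), []).append(sid)
    keys = list(groups)
    order = np.random.default_rng(seed).permutation(len(keys))
    n_total = len(index.ids)
    n_test = int(round(n_total * test_fraction))

    test_ids: List[str] = []
    rest_keys: List[str] = []
    for gi in order:
        if len(test_ids) < n_test:
            test_ids.extend(groups[keys[gi]])
        else:
            rest_keys.append(keys[gi])
    n_rest = n_total - len(test_ids)
    n_val = int(round(n_rest * val_fraction))
    val_ids: List[str] = []
    train_ids: List[str] = []
    for key in rest_keys:
        if len(val_ids) < n_val:
            val_ids.extend(groups[key])
        else:
            train_ids.extend(groups[key])
    if not (train_ids and val_ids and test_ids):
        raise SpecificationError(
            f"split produced an empty subset "
            f"(train={len(train_ids)}, val={len(val_ids)}, "
            f"test={len(test_ids)})")
    for sid in train_ids:
        index.split_of[sid] = "train"
    for sid in val_ids:
        index.split_of[sid] = "val"
    for sid in test_ids:
        index.split_of[sid] = "test"
    index.write_split_files()
    return index


# ---------------------------------------------------------------------------
# annotation preprocessing
# ---------------------------------------------------------------------------

def preprocess_annotation(mask_image: np.ndarray) -> np.ndarray:
    """Annotation-visualization preprocessing: ITU-R 601 luminance followed
    by a linear contrast stretch of the occupied range to [0, 255].

    On a constant (flat) input the stretch degenerates and the luminance is
    returned unchanged. The network itself consumes 3-channel RGB; this
    routine serves the annotation workflow only.
    """
    img = np.asarray(mask_image, dtype=np.float64)
    if img.ndim == 3:
        lum = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    else:
        lum = img
    lo, hi = lum.min(), lum.max()
    if hi > lo:
        lum = (lum - lo) * (255.0 / (hi - lo))
    return np.round(lum).clip(0, 255).astype(np.uint8)
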