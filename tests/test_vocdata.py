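"""VOC I/O, Labelme conversion, the four-strategy augmentation protocol,
dataset expansion, and leakage-safe splitting."""

import json

import numpy as np
import pytest
from PIL import Image

from rdsunet.errors import (DataIOError, FormatError, SpecificationError)
from rdsunet.scene import LabeledScene
from rdsunet.synthetic_scenes import generate_dataset, generate_scene
from rdsunet.vocdata import (AugmentationConfig, DatasetIndex, augment,
                             expand_dataset, labelme_to_voc, load_sample,
                             preprocess_annotation, read_mask_png,
                             split_dataset, write_mask_png)

from conftest import tiny_scene_spec

RNG = np.random.default_rng(31)


def _scene(seed=0, size=48):
    return generate_scene(tiny_scene_spec(image_size=size), seed)


# ---------------------------------------------------------------------------
# mask PNG + load_sample
# ---------------------------------------------------------------------------

def test_mask_png_roundtrip(tmp_path):
    mask = RNG.integers(0, 3, (32, 32)).astype(np.uint8)
    p = tmp_path / "m.png"
    write_mask_png(p, mask)
    np.testing.assert_array_equal(read_mask_png(p), mask)


def test_mask_png_out_of_range_index_raises(tmp_path):
    img = Image.fromarray(np.full((8, 8), 5, np.uint8), mode="P")
    img.putpalette([0] * 768)
    p = tmp_path / "bad.png"
    img.save(p)
    with pytest.raises(FormatError):
        read_mask_png(p)


def test_load_sample_resizes_to_224(tmp_path, tiny_dataset):
    scene = load_sample(tiny_dataset, tiny_dataset.ids[0])  # default target
    assert scene.image.shape == (224, 224, 3)
    assert scene.mask.shape == (224, 224)
    assert set(np.unique(scene.mask).tolist()) <= {0, 1, 2}


def test_load_sample_wide_input_becomes_square(tmp_path):
    index = DatasetIndex.create(tmp_path)
    img = RNG.integers(0, 255, (720, 1280, 3)).astype(np.uint8)
    mask = np.zeros((720, 1280), np.uint8)
    from rdsunet.vocdata import write_sample
    write_sample(index, "wide", LabeledScene(image=img, mask=mask))
    index.add("wide")
    scene = load_sample(index, "wide")
    assert scene.image.shape == (224, 224, 3)


def test_load_sample_missing_file_is_io_error(tmp_path):
    index = DatasetIndex.create(tmp_path)
    index.add("ghost")
    with pytest.raises(DataIOError):
        load_sample(index, "ghost")


# ---------------------------------------------------------------------------
# Labelme conversion
# ---------------------------------------------------------------------------

def _labelme(tmp_path, shapes, h=32, w=32):
    p = tmp_path / "ann.json"
    p.write_text(json.dumps({"imageHeight": h, "imageWidth": w,
                             "shapes": shapes}))
    return p


def _ray_cast_inside(pts, x, y):
    """Independent even-odd ray-casting point-in-polygon oracle."""
    inside = False
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


def test_square_corn_polygon_pixel_count(tmp_path):
    shapes = [{"label": "corn",
               "points": [[10, 10], [20, 10], [20, 20], [10, 20]]}]
    scene = labelme_to_voc(_labelme(tmp_path, shapes))
    assert int((scene.mask == 1).sum()) == 100
    assert np.all(scene.mask[10:20, 10:20] == 1)


def test_empty_shape_list_all_background(tmp_path):
    scene = labelme_to_voc(_labelme(tmp_path, []))
    assert np.all(scene.mask == 0)


def test_unknown_label_raises_format_error(tmp_path):
    shapes = [{"label": "dandelion", "points": [[0, 0], [5, 0], [5, 5]]}]
    with pytest.raises(FormatError, match="dandelion"):
        labelme_to_voc(_labelme(tmp_path, shapes))


def test_grass_maps_to_class_two_and_overwrites(tmp_path):
    shapes = [
        {"label": "corn", "points": [[2, 2], [24, 2], [24, 24], [2, 24]]},
        {"label": "grass", "points": [[10, 10], [16, 10], [16, 16], [10, 16]]},
    ]
    scene = labelme_to_voc(_labelme(tmp_path, shapes))
    assert scene.mask[12, 12] == 2          # later polygon wins
    assert scene.mask[4, 4] == 1


def test_triangle_matches_ray_casting_oracle(tmp_path):
    pts = [[3.2, 4.1], [27.5, 9.3], [12.0, 26.8]]
    scene = labelme_to_voc(_labelme(tmp_path, [{"label": "corn",
                                                "points": pts}]))
    for y in range(32):
        for x in range(32):
            expect = _ray_cast_inside(pts, x + 0.5, y + 0.5)
            assert (scene.mask[y, x] == 1) == expect, (x, y)


def test_labelme_missing_file_is_io_error(tmp_path):
    with pytest.raises(DataIOError):
        labelme_to_voc(tmp_path / "nope.json")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_p_zero_is_identity():
    scene = _scene()
    out = augment(scene, AugmentationConfig(p_apply=0.0), seed=5)
    np.testing.assert_array_equal(out.image, scene.image)
    np.testing.assert_array_equal(out.mask, scene.mask)


def test_augment_deterministic():
    scene = _scene()
    cfg = AugmentationConfig(p_apply=1.0, seed=0)
    a = augment(scene, cfg, seed=17)
    b = augment(scene, cfg, seed=17)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.mask, b.mask)


def test_augment_preserves_shape_and_classes():
    scene = _scene()
    for seed in range(10):
        out = augment(scene, AugmentationConfig(p_apply=1.0), seed=seed)
        assert out.image.shape == scene.image.shape
        assert out.mask.shape == scene.mask.shape
        assert set(np.unique(out.mask).tolist()) <= {0, 1, 2}


def test_photometric_only_changes_image_not_mask():
    # force noise on, everything else off
    scene = _scene()
    cfg = AugmentationConfig(p_apply=1.0, rotation_range=0.0,
                             brightness_range=(1.0, 1.0),
                             contrast_range=(1.0, 1.0),
                             equalize_histogram=False, motion_blur_len=1,
                             noise_sigma=12.0)
    out = augment(scene, cfg, seed=3)
    np.testing.assert_array_equal(out.mask, scene.mask)
    assert np.abs(out.image.astype(int) - scene.image.astype(int)).mean() > 0


def test_rotation_90_matches_coordinate_oracle():
    # a single off-center corn pixel must land on the rotated coordinate
    n = 33
    img = np.zeros((n, n, 3), np.uint8)
    mask = np.zeros((n, n), np.uint8)
    r, c = 6, 22
    mask[r, c] = 1
    from rdsunet.vocdata import _rotate_pair
    _, rot = _rotate_pair(img, mask, 90.0)
    # inverse-map convention about center (n-1)/2: output (r', c') draws from
    # source (cy + cos*dy + sin*dx, cx - sin*dy + cos*dx)
    cy = cx = (n - 1) / 2.0
    found = np.argwhere(rot == 1)
    assert len(found) == 1
    rp, cp = found[0]
    # forward map implied by the inverse-map convention: for +90 deg an
    # output pixel (r', c') draws from source (cy + dx', cx - dy'), so the
    # source (dy, dx) lands at (dy', dx') = (-dx, +dy)
    dy, dx = r - cy, c - cx
    assert (rp, cp) == (int(round(cy - dx)), int(round(cx + dy)))


def test_rotation_fills_mask_border_with_background():
    scene = _scene()
    cfg = AugmentationConfig(p_apply=1.0, noise_sigma=0.0,
                             rotation_range=45.0,
                             brightness_range=(1.0, 1.0),
                             contrast_range=(1.0, 1.0),
                             equalize_histogram=False, motion_blur_len=1)
    out = augment(scene, cfg, seed=2)
    assert set(np.unique(out.mask).tolist()) <= {0, 1, 2}
    # corners rotate out of frame -> background
    assert out.mask[0, 0] == 0


def test_invalid_config_raises():
    with pytest.raises(SpecificationError):
        AugmentationConfig(p_apply=1.5)
    with pytest.raises(SpecificationError):
        AugmentationConfig(brightness_range=(1.2, 0.8))


# ---------------------------------------------------------------------------
# expansion + splits
# ---------------------------------------------------------------------------

def test_expand_round_robin_counts(tmp_path):
    index = generate_dataset(tiny_scene_spec(), 3, tmp_path, seed=1)
    cfg = AugmentationConfig(target_count=7, seed=0)
    out = expand_dataset(index, cfg)
    assert len(out.ids) == 7
    reps = {sid: [] for sid in ["00000", "00001", "00002"]}
    for sid in out.ids:
        if "_aug" in sid:
            reps[out.source_of[sid]].append(sid)
    assert sorted(len(v) for v in reps.values()) == [1, 1, 2]


def test_expand_noop_at_current_count(tmp_path):
    index = generate_dataset(tiny_scene_spec(), 4, tmp_path, seed=2)
    out = expand_dataset(index, AugmentationConfig(target_count=4))
    assert out.ids == [f"{i:05d}" for i in range(4)]


def test_expand_below_current_count_raises(tmp_path):
    index = generate_dataset(tiny_scene_spec(), 4, tmp_path, seed=2)
    with pytest.raises(SpecificationError):
        expand_dataset(index, AugmentationConfig(target_count=3))


def test_split_sizes_and_disjointness(tmp_path):
    index = generate_dataset(tiny_scene_spec(), 10, tmp_path, seed=3)
    out = split_dataset(index, 0.2, 0.2, seed=0)
    tr, va, te = (out.split_ids(s) for s in ("train", "val", "test"))
    assert (len(tr), len(va), len(te)) == (6, 2, 2)
    assert set(tr) | set(va) | set(te) == set(out.ids)
    assert not (set(tr) & set(va)) and not (set(va) & set(te))


def test_split_keeps_replicates_with_source(tmp_path):
    index = generate_dataset(tiny_scene_spec(), 5, tmp_path, seed=4)
    index = expand_dataset(index, AugmentationConfig(target_count=20, seed=1))
    out = split_dataset(index, 0.2, 0.25, seed=7)
    for sid in out.ids:
        src = out.source_of.get(sid, sid)
        assert out.split_of[sid] == out.split_of[src], sid


def test_split_deterministic(tmp_path):
    index = generate_dataset(tiny_scene_spec(), 10, tmp_path, seed=5)
    a = dict(split_dataset(index, 0.2, 0.2, seed=11).split_of)
    b = dict(split_dataset(index, 0.2, 0.2, seed=11).split_of)
    assert a == b


def test_split_bad_fraction_raises(tmp_path):
    index = generate_dataset(tiny_scene_spec(), 10, tmp_path, seed=5)
    with pytest.raises(SpecificationError):
        split_dataset(index, 0.0, 0.2, seed=0)


# ---------------------------------------------------------------------------
# annotation preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_constant_input_unchanged():
    img = np.full((8, 8, 3), 77, np.uint8)
    out = preprocess_annotation(img)
    assert np.all(out == out[0, 0])


def test_preprocess_green_brighter_than_red():
    img = np.zeros((1, 2, 3), np.uint8)
    img[0, 0] = (255, 0, 0)   # red
    img[0, 1] = (0, 255, 0)   # green
    out = preprocess_annotation(img)
    assert out[0, 1] > out[0, 0]


def test_preprocess_stretches_range_to_0_255():
    img = np.stack([np.linspace(50, 150, 64).reshape(8, 8)] * 3,
                   axis=-1).astype(np.uint8)
    out = preprocess_annotation(img)
    assert out.min() == 0
    assert out.max() == 255
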