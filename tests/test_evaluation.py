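"""MIoU/precision/recall vs per-pixel brute-force oracles, FPS utility, overlays."""

from fractions import Fraction

import numpy as np
import pytest

from rdsunet.errors import (ShapeError, SpecificationError,
                            UndefinedMetricError)
from rdsunet.evaluation import (ConfusionMatrix, accumulate_confusion,
                                evaluate_masks, make_panel, measure_fps, miou,
                                per_class_iou, per_class_precision_recall,
                                precision_recall, render_overlay,
                                write_metrics_report)

RNG = np.random.default_rng(51)


def _brute_metrics(pred, truth, k=3):
    """Exact rational per-pixel loop oracle for MIoU/precision/recall."""
    tp = [0] * k
    fp = [0] * k
    fn = [0] * k
    for p, t in zip(pred.ravel().tolist(), truth.ravel().tolist()):
        if p == t:
            tp[p] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    ious, precs, recs = [], [], []
    for c in range(k):
        if tp[c] + fp[c] + fn[c] > 0:
            ious.append(Fraction(tp[c], tp[c] + fp[c] + fn[c]))
        if tp[c] + fp[c] > 0:
            precs.append(Fraction(tp[c], tp[c] + fp[c]))
        if tp[c] + fn[c] > 0:
            recs.append(Fraction(tp[c], tp[c] + fn[c]))
    mean = lambda xs: sum(xs) / len(xs)
    return mean(ious), mean(precs), mean(recs)


# ---------------------------------------------------------------------------
# confusion accumulation
# ---------------------------------------------------------------------------

def test_perfect_prediction_diagonal():
    truth = RNG.integers(0, 3, (8, 8))
    cm = accumulate_confusion(truth, truth)
    assert cm.counts.trace() == 64
    assert (cm.counts.sum() - cm.counts.trace()) == 0


def test_hand_enumerated_two_by_two():
    truth = np.array([[0, 1], [2, 2]])
    pred = np.array([[0, 2], [2, 1]])
    cm = accumulate_confusion(pred, truth)
    assert cm.counts[0, 0] == 1
    assert cm.counts[1, 2] == 1
    assert cm.counts[2, 2] == 1
    assert cm.counts[2, 1] == 1
    assert cm.total == 4


def test_accumulation_additive_over_batches():
    a_p, a_t = RNG.integers(0, 3, (2, 6, 6))
    b_p, b_t = RNG.integers(0, 3, (2, 6, 6))
    cm1 = accumulate_confusion(b_p, b_t, accumulate_confusion(a_p, a_t))
    cm2 = accumulate_confusion(np.concatenate([a_p, b_p]),
                               np.concatenate([a_t, b_t]))
    np.testing.assert_array_equal(cm1.counts, cm2.counts)


def test_shape_mismatch_raises():
    with pytest.raises(ShapeError):
        accumulate_confusion(np.zeros((3, 3), int), np.zeros((4, 4), int))


def test_out_of_range_class_raises():
    with pytest.raises(ShapeError):
        accumulate_confusion(np.full((2, 2), 7), np.zeros((2, 2), int))


# ---------------------------------------------------------------------------
# miou / precision / recall
# ---------------------------------------------------------------------------

def test_perfect_prediction_scores_one():
    truth = RNG.integers(0, 3, (10, 10))
    cm = accumulate_confusion(truth, truth)
    assert miou(cm) == 1.0
    assert precision_recall(cm) == (1.0, 1.0)


def test_four_pixel_toy_hand_computation():
    truth = np.array([1, 1, 0, 0])
    pred = np.array([1, 0, 0, 0])
    cm = accumulate_confusion(pred, truth, ConfusionMatrix(n_classes=2))
    ious = per_class_iou(cm)
    assert ious[0] == pytest.approx(2 / 3)
    assert ious[1] == pytest.approx(1 / 2)
    assert miou(cm) == pytest.approx(7 / 12)
    prec, rec = per_class_precision_recall(cm)
    assert prec[1] == 1.0 and rec[1] == 0.5
    assert prec[0] == pytest.approx(2 / 3) and rec[0] == 1.0
    mp, mr = precision_recall(cm)
    assert mp == pytest.approx(5 / 6)
    assert mr == pytest.approx(3 / 4)


def test_relabeling_invariance():
    truth = RNG.integers(0, 3, (12, 12))
    pred = RNG.integers(0, 3, (12, 12))
    perm = np.array([2, 0, 1])
    m1 = miou(accumulate_confusion(pred, truth))
    m2 = miou(accumulate_confusion(perm[pred], perm[truth]))
    assert m1 == pytest.approx(m2)


def test_swap_pred_truth_swaps_precision_recall():
    truth = RNG.integers(0, 3, (9, 9))
    pred = RNG.integers(0, 3, (9, 9))
    p1, r1 = precision_recall(accumulate_confusion(pred, truth))
    p2, r2 = precision_recall(accumulate_confusion(truth, pred))
    assert p1 == pytest.approx(r2)
    assert r1 == pytest.approx(p2)


def test_absent_class_excluded_from_mean():
    truth = np.array([0, 0, 1, 1])   # class 2 never appears
    pred = np.array([0, 1, 1, 1])
    cm = accumulate_confusion(pred, truth)
    assert np.isnan(per_class_iou(cm)[2])
    oracle_miou, _, _ = _brute_metrics(pred, truth)
    assert miou(cm) == pytest.approx(float(oracle_miou))


def test_empty_matrix_raises_undefined():
    with pytest.raises(UndefinedMetricError):
        miou(ConfusionMatrix())


def test_metrics_match_brute_force_on_random_masks():
    # exact rational agreement on 200 random 16x16 pairs
    for trial in range(200):
        rng = np.random.default_rng(trial)
        truth = rng.integers(0, 3, (16, 16))
        pred = rng.integers(0, 3, (16, 16))
        cm = accumulate_confusion(pred, truth)
        om, op, orc = _brute_metrics(pred, truth)
        assert miou(cm) == pytest.approx(float(om), abs=1e-12)
        mp, mr = precision_recall(cm)
        assert mp == pytest.approx(float(op), abs=1e-12)
        assert mr == pytest.approx(float(orc), abs=1e-12)


def test_foreground_mode_restricts_classes():
    truth = np.array([0, 0, 1, 2])
    pred = np.array([0, 1, 1, 2])
    cm = accumulate_confusion(pred, truth)
    p, r = precision_recall(cm, mode="foreground")
    assert p == pytest.approx((0.5 + 1.0) / 2)
    assert r == pytest.approx(1.0)
    with pytest.raises(SpecificationError):
        precision_recall(cm, mode="micro")


# ---------------------------------------------------------------------------
# fps utility
# ---------------------------------------------------------------------------

def test_fps_zero_frames_raises():
    from rdsunet.network import build_model
    model = build_model("unet", seed=0)
    with pytest.raises(SpecificationError):
        measure_fps(model, image_size=32, n_frames=0)


def test_fps_positive_finite_with_hardware_descriptor():
    from rdsunet.network import build_model
    model = build_model("unet", seed=0)
    out = measure_fps(model, image_size=32, n_frames=2, warmup=1)
    assert out["fps"] > 0 and np.isfinite(out["fps"])
    assert isinstance(out["hardware"], str) and out["hardware"]


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

def test_overlay_background_untouched():
    img = RNG.integers(0, 255, (10, 10, 3)).astype(np.uint8)
    out = render_overlay(img, np.zeros((10, 10), np.uint8))
    np.testing.assert_array_equal(out, img)


def test_overlay_single_corn_pixel_green_shifted():
    img = np.full((5, 5, 3), 100, np.uint8)
    mask = np.zeros((5, 5), np.uint8)
    mask[2, 3] = 1
    out = render_overlay(img, mask, alpha=0.5)
    np.testing.assert_array_equal(out[2, 3], [50, 178, 50])
    untouched = out.copy()
    untouched[2, 3] = 100
    np.testing.assert_array_equal(untouched, img)


def test_weed_pixels_red_shifted():
    img = np.full((4, 4, 3), 100, np.uint8)
    mask = np.zeros((4, 4), np.uint8)
    mask[1, 1] = 2
    out = render_overlay(img, mask, alpha=0.5)
    np.testing.assert_array_equal(out[1, 1], [178, 50, 50])


def test_panel_width_three_images_plus_separators():
    img = RNG.integers(0, 255, (8, 8, 3)).astype(np.uint8)
    mask = np.zeros((8, 8), np.uint8)
    panel = make_panel(img, mask, mask, sep=2)
    assert panel.shape == (8, 3 * 8 + 2 * 2, 3)


def test_metrics_report_file(tmp_path):
    p = tmp_path / "report.tsv"
    write_metrics_report(p, {"miou": 0.5, "precision": 0.25, "recall": 0.75,
                             "fps": 1.5})
    text = p.read_text()
    assert "miou_percent\t50.00" in text
    assert "precision_percent\t25.00" in text
    assert "recall_percent\t75.00" in text
    assert "fps\t1.5" in text


def test_evaluate_masks_end_to_end():
    truth = RNG.integers(0, 3, (3, 8, 8))
    out = evaluate_masks(truth, truth)
    assert out["miou"] == 1.0
    assert out["pixels"] == 3 * 64
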