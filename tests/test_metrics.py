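"""Metric implementations vs explicit all-pairs / per-pixel loop oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from msanet import classification_report, dice_score, hd95, pixel_precision_recall
from msanet.metrics import ConfusionCounts, boundary_pixels, hd95_flagged


# -- oracles ---------------------------------------------------------------

def loop_confusion(pred, true):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and true[i, j]:
                tp += 1
            elif pred[i, j]:
                fp += 1
            elif true[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def boundary_oracle(mask):
    """Foreground pixels with at least one background 4-neighbor."""
    pts = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    pts.append((i, j))
                    break
    return np.array(pts) if pts else np.empty((0, 2), dtype=int)


def hd95_oracle(pred, true, spacing=(1.0, 1.0)):
    bp = boundary_oracle(pred) * np.asarray(spacing)
    bt = boundary_oracle(true) * np.asarray(spacing)
    d = cdist(bp, bt)
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


def random_mask(rng, shape, p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


# -- dice ------------------------------------------------------------------

def test_dice_identical_and_disjoint():
    a = np.zeros((6, 6), dtype=np.uint8)
    a[1:4, 1:4] = 1
    b = np.zeros_like(a)
    b[4:6, 4:6] = 1
    assert dice_score(a, a) == 1.0
    assert dice_score(a, b) == 0.0
    assert dice_score(np.zeros_like(a), np.zeros_like(a)) == 1.0


def test_dice_shifted_square_hand_count():
    # 2x2 squares shifted one column: areas 4 and 4, overlap 2 -> dice 0.5
    a = np.zeros((5, 5), dtype=np.uint8)
    a[1:3, 1:3] = 1
    b = np.zeros_like(a)
    b[1:3, 2:4] = 1
    assert dice_score(a, b) == pytest.approx(0.5)


def test_dice_symmetry_and_harmonic_identity():
    rng = np.random.default_rng(31)
    for _ in range(25):
        a, b = random_mask(rng, (12, 12)), random_mask(rng, (12, 12))
        assert dice_score(a, b) == dice_score(b, a)
        p, r = pixel_precision_recall(a, b)
        if p + r > 0:
            assert dice_score(a, b) == pytest.approx(2 * p * r / (p + r), abs=1e-9)


# -- precision / recall ----------------------------------------------------

def test_pixel_precision_recall_oracle_agreement():
    rng = np.random.default_rng(32)
    for _ in range(50):
        a, b = random_mask(rng, (10, 10)), random_mask(rng, (10, 10))
        tp, fp, fn, _ = loop_confusion(a, b)
        p, r = pixel_precision_recall(a, b)
        if tp + fp:
            assert p == pytest.approx(tp / (tp + fp), abs=1e-12)
        if tp + fn:
            assert r == pytest.approx(tp / (tp + fn), abs=1e-12)


def test_overprediction_halves_precision():
    true = np.zeros((8, 8), dtype=np.uint8)
    true[2:4, 2:4] = 1  # area 4
    pred = np.zeros_like(true)
    pred[2:4, 2:6] = 1  # area 8, superset
    p, r = pixel_precision_recall(pred, true)
    assert (p, r) == (0.5, 1.0)


def test_empty_denominator_conventions():
    empty = np.zeros((4, 4), dtype=np.uint8)
    some = empty.copy()
    some[1, 1] = 1
    assert pixel_precision_recall(empty, empty) == (1.0, 1.0)
    assert pixel_precision_recall(empty, some) == (0.0, 0.0)


# -- hd95 ------------------------------------------------------------------

def test_hd95_identical_masks_is_zero():
    a = np.zeros((9, 9), dtype=np.uint8)
    a[2:6, 3:7] = 1
    assert hd95(a, a) == 0.0


def test_hd95_two_single_pixels():
    a = np.zeros((8, 8), dtype=np.uint8)
    b = np.zeros_like(a)
    a[2, 2] = 1
    b[2, 5] = 1
    assert hd95(a, b) == pytest.approx(3.0)


def test_hd95_shifted_square_matches_all_pairs_oracle():
    a = np.zeros((16, 16), dtype=np.uint8)
    a[3:13, 3:13] = 1
    b = np.roll(a, 2, axis=1)
    assert hd95(a, b) == pytest.approx(hd95_oracle(a, b), abs=1e-9)


def test_hd95_oracle_agreement_on_random_masks():
    rng = np.random.default_rng(33)
    checked = 0
    while checked < 50:
        shape = (int(rng.integers(8, 33)), int(rng.integers(8, 33)))
        a = random_mask(rng, shape, p=0.25)
        b = random_mask(rng, shape, p=0.25)
        if not a.any() or not b.any():
            continue
        spacing = (float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.5, 2.0)))
        assert hd95(a, b, spacing) == pytest.approx(
            hd95_oracle(a, b, spacing), abs=1e-9)
        checked += 1


def test_hd95_symmetry():
    rng = np.random.default_rng(34)
    a, b = random_mask(rng, (14, 14)), random_mask(rng, (14, 14))
    assert hd95(a, b) == pytest.approx(hd95(b, a), abs=1e-12)


def test_hd95_empty_side_sentinel_is_image_diagonal():
    empty = np.zeros((3, 4), dtype=np.uint8)
    some = empty.copy()
    some[1, 1] = 1
    val, degenerate = hd95_flagged(some, empty)
    assert degenerate and val == pytest.approx(5.0)
    val, degenerate = hd95_flagged(empty, empty)
    assert not degenerate and val == 0.0


def test_boundary_matches_loop_definition():
    rng = np.random.default_rng(35)
    for _ in range(10):
        m = random_mask(rng, (9, 9), p=0.45)
        got = {tuple(p) for p in boundary_pixels(m)}
        want = {tuple(p) for p in boundary_oracle(m)}
        assert got == want


# -- patient-level classification -----------------------------------------

def test_classification_report_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(36)
    preds = rng.integers(0, 2, size=40)
    truths = rng.integers(0, 2, size=40)
    acc, prec, rec, f1 = classification_report(preds, truths)
    assert acc == pytest.approx(sk.accuracy_score(truths, preds))
    assert prec == pytest.approx(sk.precision_score(truths, preds))
    assert rec == pytest.approx(sk.recall_score(truths, preds))
    assert f1 == pytest.approx(sk.f1_score(truths, preds))


def test_all_correct_and_all_wrong():
    labels = np.array([1, 0, 1, 1, 0])
    assert classification_report(labels, labels) == (1.0, 1.0, 1.0, 1.0)
    acc, _, _, _ = classification_report(1 - labels, labels)
    assert acc == 0.0


def test_f1_is_harmonic_mean_of_returned_precision_recall():
    rng = np.random.default_rng(37)
    for _ in range(20):
        preds = rng.integers(0, 2, size=15)
        truths = rng.integers(0, 2, size=15)
        _, p, r, f1 = classification_report(preds, truths)
        if p + r:
            assert f1 == pytest.approx(2 * p * r / (p + r), abs=1e-9)


def test_confusion_counts_validation():
    with pytest.raises(ValueError, match="non-negative"):
        ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)
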