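"""Hybrid loss closed forms, deep-supervision weighting, and overlap metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from r2upp.losses import (
    LossConfig,
    MaskPair,
    MetricsReport,
    accuracy,
    aggregate_reports,
    binarize,
    confusion_counts,
    dice,
    hybrid_loss,
    hybrid_loss_tensor,
    iou,
    sensitivity,
    specificity,
    total_loss,
    write_metrics_csv,
    write_metrics_json,
)
from r2upp.autodiff import Tensor


def test_perfect_all_foreground_scores_minus_one():
    pair = MaskPair(np.ones((8, 8)), np.ones((8, 8)))
    assert hybrid_loss(pair) == pytest.approx(-1.0)


def test_perfect_all_background_scores_zero():
    eps = LossConfig().probability_floor
    pair = MaskPair(np.zeros((8, 8)), np.full((8, 8), eps))
    assert hybrid_loss(pair) == pytest.approx(0.0, abs=1e-6)


def test_single_pixel_hand_evaluation():
    """y=1, p=0.5: -(ln 0.5 + 2*0.5/(1+0.25)) = -0.10685."""
    expected = -(math.log(0.5) + 2 * 0.5 / (1 + 0.25))
    pair = MaskPair(np.ones((1, 1)), np.full((1, 1), 0.5))
    assert hybrid_loss(pair) == pytest.approx(expected, rel=1e-6)
    assert expected == pytest.approx(-0.10685, abs=5e-5)


def test_loss_is_finite_at_extremes():
    pair = MaskPair(np.ones((4, 4)), np.zeros((4, 4)))
    assert np.isfinite(hybrid_loss(pair))
    pair = MaskPair(np.zeros((4, 4)), np.ones((4, 4)))
    assert np.isfinite(hybrid_loss(pair))


def test_loss_bounded_below_and_minimized_at_target(rng):
    y = (rng.random((16, 16)) > 0.5).astype(float)
    base = hybrid_loss(MaskPair(y, y))
    # at P = Y each foreground pixel contributes -1 (dice reward), background 0
    assert base == pytest.approx(-y.mean(), abs=1e-6)
    assert base >= -1.0 - 1e-9
    for _ in range(5):  # random perturbations away from the target increase the loss
        p = np.clip(y + rng.normal(0, 0.1, y.shape), 0, 1)
        assert hybrid_loss(MaskPair(y, p)) >= base - 1e-12


def test_tensor_loss_matches_plain_loss(rng):
    y = (rng.random((2, 1, 8, 8)) > 0.4).astype(float)
    p = rng.random((2, 1, 8, 8))
    plain = hybrid_loss(MaskPair(y, p))
    tens = float(hybrid_loss_tensor(Tensor(p), y).data)
    assert tens == pytest.approx(plain, rel=1e-6)


def test_total_loss_sums_heads(rng):
    y = (rng.random((8, 8)) > 0.5).astype(float)
    pairs = [MaskPair(y, rng.random((8, 8))) for _ in range(4)]
    individual = [hybrid_loss(p) for p in pairs]
    assert total_loss(pairs) == pytest.approx(sum(individual), rel=1e-9)
    last_only = total_loss(pairs, LossConfig(head_weights=(0, 0, 0, 1)))
    assert last_only == pytest.approx(individual[-1], rel=1e-9)


def test_total_loss_linear_in_eta(rng):
    y = (rng.random((8, 8)) > 0.5).astype(float)
    pairs = [MaskPair(y, rng.random((8, 8))) for _ in range(3)]
    eta = (0.5, 2.0, 1.5)
    expected = sum(w * hybrid_loss(p) for w, p in zip(eta, pairs))
    assert total_loss(pairs, LossConfig(head_weights=eta)) == pytest.approx(expected, rel=1e-9)


def test_identical_heads_sum_to_d_times_loss(rng):
    y = (rng.random((8, 8)) > 0.5).astype(float)
    p = rng.random((8, 8))
    pair = MaskPair(y, p)
    assert total_loss([pair] * 4) == pytest.approx(4 * hybrid_loss(pair), rel=1e-9)


def test_maskpair_validation():
    with pytest.raises(ValueError, match="shapes"):
        MaskPair(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError, match="binary"):
        MaskPair(np.full((2, 2), 0.5), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="lie in"):
        MaskPair(np.ones((2, 2)), np.full((2, 2), 1.5))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_confusion_counts_trivial_cases():
    ones = np.ones((10, 10), dtype=np.uint8)
    zeros = np.zeros((10, 10), dtype=np.uint8)
    assert confusion_counts(ones, ones) == (100, 0, 0, 0)
    assert confusion_counts(ones, zeros) == (0, 0, 0, 100)


def test_confusion_counts_vs_quadruple_loop(rng):
    gt = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    pr = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    tp = tn = fp = fn = 0
    for i in range(16):
        for j in range(16):
            if gt[i, j] and pr[i, j]:
                tp += 1
            elif not gt[i, j] and not pr[i, j]:
                tn += 1
            elif not gt[i, j] and pr[i, j]:
                fp += 1
            else:
                fn += 1
    assert confusion_counts(gt, pr) == (tp, tn, fp, fn)


def test_dice_iou_hand_counts():
    gt = np.zeros((4, 4), dtype=np.uint8)
    pr = np.zeros((4, 4), dtype=np.uint8)
    gt[0, 0] = gt[0, 1] = 1
    pr[0, 1] = pr[0, 2] = 1
    assert dice(gt, pr) == pytest.approx(0.5)
    assert iou(gt, pr) == pytest.approx(1 / 3)


def test_identical_and_disjoint_masks():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[1:3, 1:3] = 1
    assert dice(m, m) == 1.0 and iou(m, m) == 1.0
    other = np.zeros_like(m)
    other[4, 4] = 1
    assert dice(m, other) == 0.0 and iou(m, other) == 0.0


def test_empty_mask_conventions():
    empty = np.zeros((4, 4), dtype=np.uint8)
    assert dice(empty, empty) == 1.0
    assert iou(empty, empty) == 1.0
    assert sensitivity(empty, empty) == 1.0
    assert specificity(np.ones((4, 4), dtype=np.uint8), np.ones((4, 4), dtype=np.uint8)) == 1.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_dice_iou_identity_randomized(seed):
    """Dice = 2*IoU / (1 + IoU) for arbitrary binary masks."""
    r = np.random.default_rng(seed)
    gt = (r.random((12, 12)) > r.random()).astype(np.uint8)
    pr = (r.random((12, 12)) > r.random()).astype(np.uint8)
    i = iou(gt, pr)
    assert dice(gt, pr) == pytest.approx(2 * i / (1 + i), abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_complement_exchanges_sensitivity_specificity(seed):
    r = np.random.default_rng(seed)
    gt = (r.random((10, 10)) > 0.5).astype(np.uint8)
    pr = (r.random((10, 10)) > 0.5).astype(np.uint8)
    assert sensitivity(gt, pr) == pytest.approx(specificity(1 - gt, 1 - pr))
    for metric in (dice, iou, accuracy, sensitivity, specificity):
        assert 0.0 <= metric(gt, pr) <= 1.0


def test_binarize():
    assert binarize(np.full((3, 3), 0.5)).all()  # boundary convention: >= threshold
    assert not binarize(np.zeros((3, 3))).any()
    r = np.random.default_rng(0).random((6, 6))
    expected = np.array([[1 if v >= 0.5 else 0 for v in row] for row in r])
    np.testing.assert_array_equal(binarize(r), expected)
    with pytest.raises(ValueError):
        binarize(np.full((2, 2), 1.5))


def test_report_writers(tmp_path, rng):
    gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    pr = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    reports = {f"img{i}": MetricsReport.from_masks(gt, pr) for i in range(3)}
    csv_path = tmp_path / "metrics.csv"
    json_path = tmp_path / "metrics.json"
    write_metrics_csv(reports, csv_path)
    write_metrics_json(list(reports.values()), json_path)
    lines = csv_path.read_text().strip().splitlines()
    assert len(lines) == 4 and lines[0].startswith("id,dice")
    agg = aggregate_reports(reports.values())
    assert agg["dice"]["sd"] == pytest.approx(0.0, abs=1e-12)  # identical reports
    assert json_path.exists()
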