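"""Hybrid segmentation loss, deep-supervision total loss, and overlap metrics.

The per-head loss combines pixel-wise cross-entropy with a soft Dice
reward, summed per pixel and class:

    L(Y, P) = -(1/N) sum_c sum_n [ y_nc log p_nc + 2 y_nc p_nc / (y_nc^2 + p_nc^2) ]

where Y are one-hot labels, P predicted probabilities, N the pixel count
and C the class count.  For the single-class sigmoid case the
cross-entropy summand is completed to the full binary form
``y log p + (1-y) log(1-p)``: the one-hot categorical sum covers the
background through its own class only when C > 1, and without the
``(1-y)`` term background pixels would incur no penalty at all, making
"everything foreground" a global optimum.  The completion leaves the
loss's closed-form anchor values unchanged (perfect all-foreground -> -1
per class, perfect all-background -> 0 up to the probability floor).

The Dice summand is evaluated *per pixel* inside the double sum (so a
perfect all-foreground prediction scores -C); the conventional per-image
soft-Dice ratio of sums is available via ``LossConfig.dice_mode =
"per_image"``.  With deep supervision the total loss is the eta-weighted
sum of the per-head losses (all eta = 1 by default).

Evaluation metrics on binary masks: Dice = 2|GT∩PR| / (|GT|+|PR|),
IoU = |GT∩PR| / |GT∪PR|, plus accuracy, sensitivity and specificity from
the pixel confusion counts.  Empty-denominator conventions: two empty
masks score Dice = IoU = 1; sensitivity with no positives in GT (and
specificity with no negatives) is reported as 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, grad_enabled

#: clamp applied to probabilities inside the log term only
PROB_FLOOR = 1e-7


@dataclass(frozen=True)
class LossConfig:
    head_weights: tuple = ()  # empty = all ones, matched to head count at call time
    num_classes: int = 1
    probability_floor: float = PROB_FLOOR
    dice_mode: str = "per_pixel"  # "per_pixel" (printed form) or "per_image"

    def __post_init__(self):
        object.__setattr__(self, "head_weights", tuple(float(w) for w in self.head_weights))
        if any(w < 0 for w in self.head_weights):
            raise ValueError("head weights must be non-negative")
        if self.dice_mode not in ("per_pixel", "per_image"):
            raise ValueError(f"unknown dice_mode {self.dice_mode!r}")


@dataclass(frozen=True)
class MaskPair:
    """One supervised head's (ground truth, prediction) pair.

    Arrays may be (H, W), (N, H, W) or (N, C, H, W); ground truth binary
    (one-hot over C when C > 1), predictions in [0, 1].
    """

    ground_truth: np.ndarray
    prediction: np.ndarray

    def __post_init__(self):
        gt = np.asarray(self.ground_truth)
        pr = np.asarray(self.prediction)
        if gt.shape != pr.shape:
            raise ValueError(f"mask shapes differ: {gt.shape} vs {pr.shape}")
        if not np.isin(gt, (0, 1)).all():
            raise ValueError("ground truth must be binary")
        if pr.min() < 0 or pr.max() > 1:
            raise ValueError("predictions must lie in [0, 1]")
        object.__setattr__(self, "ground_truth", gt)
        object.__setattr__(self, "prediction", pr)


def _hybrid_terms(y: np.ndarray, p: np.ndarray, cfg: LossConfig):
    """Per-element cross-entropy and dice summands.

    For a single sigmoid class the cross-entropy is the full binary form
    ``y log p + (1-y) log(1-p)``; with C > 1 one-hot classes it is the
    categorical form ``y log p`` (the background is then its own class).
    """
    eps = cfg.probability_floor
    p_log = np.clip(p, eps, 1.0 - eps)
    ce = y * np.log(p_log)
    if cfg.num_classes == 1:
        ce = ce + (1.0 - y) * np.log1p(-p_log)
    denom = y * y + p * p
    safe = denom > 0
    dice = np.where(safe, 2.0 * y * p / np.where(safe, denom, 1.0), 0.0)
    return ce, dice


def hybrid_loss(pair: MaskPair, cfg: LossConfig | None = None) -> float:
    """Hybrid cross-entropy + soft-Dice loss of a single head (a plain float)."""
    cfg = cfg or LossConfig()
    y = pair.ground_truth.astype(np.float64)
    p = pair.prediction.astype(np.float64)
    n_pixels = _pixel_count(y, cfg.num_classes)
    ce, dice = _hybrid_terms(y, p, cfg)
    if cfg.dice_mode == "per_pixel":
        return float(-(ce.sum() + dice.sum()) / n_pixels)
    # per-image variant: conventional ratio-of-sums soft Dice per class
    inter = (y * p).sum()
    norm = (y * y).sum() + (p * p).sum()
    soft_dice = 2.0 * inter / norm if norm > 0 else 1.0
    return float(-(ce.sum() / n_pixels) - soft_dice)


def _pixel_count(y: np.ndarray, num_classes: int) -> int:
    n = y.size
    if num_classes > 1:
        if y.ndim < 3 or y.shape[-3] != num_classes:
            raise ValueError("multi-class masks must carry a class axis of length C")
        n //= num_classes
    return n


def total_loss(head_pairs, cfg: LossConfig | None = None) -> float:
    """Weighted sum of per-head hybrid losses (deep supervision, eta_i >= 0)."""
    head_pairs = list(head_pairs)
    cfg = cfg or LossConfig()
    weights = cfg.head_weights or (1.0,) * len(head_pairs)
    if len(weights) != len(head_pairs):
        raise ValueError(f"{len(head_pairs)} heads but {len(weights)} weights")
    return float(sum(w * hybrid_loss(pair, cfg) for w, pair in zip(weights, head_pairs)))


def hybrid_loss_tensor(p: Tensor, y: np.ndarray, cfg: LossConfig | None = None) -> Tensor:
    """Differentiable hybrid loss on a prediction tensor (training path).

    Gradient of the per-pixel dice summand: d/dp [2yp/(y^2+p^2)] =
    2y(y^2 - p^2)/(y^2 + p^2)^2, zero where y = p = 0 by continuity.
    """
    cfg = cfg or LossConfig()
    if cfg.dice_mode != "per_pixel":
        raise NotImplementedError("training path implements the per-pixel dice form")
    y = np.asarray(y, dtype=p.data.dtype)
    if y.shape != p.data.shape:
        raise ValueError(f"target shape {y.shape} != prediction shape {p.data.shape}")
    eps = cfg.probability_floor
    n_pixels = _pixel_count(y, cfg.num_classes)
    ce, dice = _hybrid_terms(y, p.data, cfg)
    value = -(ce.sum() + dice.sum()) / n_pixels
    if not grad_enabled():
        return Tensor(np.asarray(value, dtype=p.data.dtype))

    def backward(g):
        pd = p.data
        p_log = np.clip(pd, eps, 1.0 - eps)
        in_range = (pd >= eps) & (pd <= 1.0 - eps)
        dce = np.where(in_range, y / p_log, 0.0)
        if cfg.num_classes == 1:
            dce = dce - np.where(in_range, (1.0 - y) / (1.0 - p_log), 0.0)
        denom = y * y + pd * pd
        safe = denom > 0
        ddice = np.where(safe, 2.0 * y * (y * y - pd * pd) / np.where(safe, denom, 1.0) ** 2, 0.0)
        return ((-g / n_pixels) * (dce + ddice).astype(pd.dtype),)

    return Tensor(np.asarray(value, dtype=p.data.dtype), parents=(p,), backward=backward)


# ---------------------------------------------------------------------------
# binary-mask metrics
# ---------------------------------------------------------------------------


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities to {0,1}; pixels >= threshold are foreground."""
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    return (prob_map >= threshold).astype(np.uint8)


def _check_binary(gt, pr):
    gt = np.asarray(gt)
    pr = np.asarray(pr)
    if gt.shape != pr.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {pr.shape}")
    for name, m in (("ground truth", gt), ("prediction", pr)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    return gt.astype(bool), pr.astype(bool)


def confusion_counts(gt, pr):
    """Pixel-wise (TP, TN, FP, FN); the four always sum to the pixel count."""
    gt, pr = _check_binary(gt, pr)
    tp = int(np.count_nonzero(gt & pr))
    tn = int(np.count_nonzero(~gt & ~pr))
    fp = int(np.count_nonzero(~gt & pr))
    fn = int(np.count_nonzero(gt & ~pr))
    return tp, tn, fp, fn


def dice(gt, pr) -> float:
    gt, pr = _check_binary(gt, pr)
    denom = gt.sum() + pr.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(gt & pr) / float(denom)


def iou(gt, pr) -> float:
    gt, pr = _check_binary(gt, pr)
    union = np.count_nonzero(gt | pr)
    if union == 0:
        return 1.0
    return np.count_nonzero(gt & pr) / float(union)


def accuracy(gt, pr) -> float:
    tp, tn, fp, fn = confusion_counts(gt, pr)
    return (tp + tn) / float(tp + tn + fp + fn)


def sensitivity(gt, pr) -> float:
    tp, _, _, fn = confusion_counts(gt, pr)
    return tp / float(tp + fn) if tp + fn else 1.0


def specificity(gt, pr) -> float:
    _, tn, fp, _ = confusion_counts(gt, pr)
    return tn / float(tn + fp) if tn + fp else 1.0


@dataclass
class MetricsReport:
    dice: float
    iou: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    METRIC_NAMES = ("dice", "iou", "accuracy", "sensitivity", "specificity")

    @classmethod
    def from_masks(cls, gt, pr) -> "MetricsReport":
        tp, tn, fp, fn = confusion_counts(gt, pr)
        return cls(
            dice=dice(gt, pr),
            iou=iou(gt, pr),
            accuracy=accuracy(gt, pr),
            sensitivity=sensitivity(gt, pr),
            specificity=specificity(gt, pr),
            tp=tp, tn=tn, fp=fp, fn=fn,
        )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}


def multiclass_report(gt_onehot: np.ndarray, pr_onehot: np.ndarray):
    """Per-class reports plus the macro average, for one-hot (C, ...) masks."""
    if gt_onehot.shape != pr_onehot.shape:
        raise ValueError("one-hot masks must share a shape")
    per_class = [MetricsReport.from_masks(gt_onehot[c], pr_onehot[c]) for c in range(gt_onehot.shape[0])]
    macro = {
        name: float(np.mean([r.as_dict()[name] for r in per_class]))
        for name in MetricsReport.METRIC_NAMES
    }
    return per_class, macro


def aggregate_reports(reports) -> dict:
    """Mean and standard deviation per metric across a list of reports.

    sd uses the sample convention (ddof=1) and is 0 for a single report.
    """
    reports = list(reports)
    out = {}
    for name in MetricsReport.METRIC_NAMES:
        values = np.array([r.as_dict()[name] for r in reports], dtype=float)
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        out[name] = {"mean": float(values.mean()), "sd": sd, "n": len(values)}
    return out


def write_metrics_csv(rows: dict, path) -> None:
    """Per-image CSV: image id followed by the five metrics."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *MetricsReport.METRIC_NAMES])
        for image_id, report in rows.items():
            writer.writerow([image_id, *(f"{report.as_dict()[m]:.6f}" for m in MetricsReport.METRIC_NAMES)])


def write_metrics_json(reports, path) -> None:
    Path(path).write_text(json.dumps(aggregate_reports(reports), indent=2))
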