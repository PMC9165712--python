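"""Training loop, repeated-trial evaluation protocol, and full-image inference.

Training minimizes the deep-supervision total loss (all head weights 1 by
default) with Adam (default learning rate 3e-4), stopping early when the
validation loss has not improved for ``early_stop_patience`` epochs and
restoring the best-validation weights.  ``run_trials`` repeats the whole
procedure with per-trial weight re-initialization (trial seed = base seed
+ trial index; data split held fixed) and reports each metric as
mean +/- sd over trials (sample sd, 0 for a single trial).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import autodiff as ad
from .losses import MetricsReport, binarize, hybrid_loss_tensor
from .network import NetworkConfig, SegmentationNetwork, build_baseline, ensemble_predict
from .nn import Adam
from .patches import ImageRecord, PatchSpec, make_grid, pad_for_full_coverage, stitch_patches
from .synthetic import SyntheticDataset, SyntheticTaskConfig, generate, generate_multiscale, train_val_test_split


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    batch_size: int = 16
    max_epochs: int = 150
    early_stop_patience: int = 10
    deep_supervision: bool = True
    head_weights: tuple = ()  # empty = all ones
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrialSummary:
    per_trial: list
    aggregate: dict
    trial_seeds: list
    histories: list = field(default_factory=list)

    @property
    def n_trials(self):
        return len(self.per_trial)


def _as_arrays(data):
    """Accept a SyntheticDataset, list of ImageRecords, or (images, masks)."""
    if isinstance(data, SyntheticDataset):
        return data.images(), data.masks()
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], ImageRecord):
        return np.stack([r.pixels for r in data]), np.stack([r.mask for r in data])
    images, masks = data
    return np.asarray(images), np.asarray(masks)


def _batch_loss(net: SegmentationNetwork, images, masks, cfg: TrainConfig):
    """Differentiable total loss over all supervised heads of a batch."""
    heads = net.forward(images)
    levels = sorted(heads)
    weights = cfg.head_weights or (1.0,) * len(levels)
    if len(weights) != len(levels):
        raise ValueError(f"{len(levels)} heads but {len(weights)} head weights")
    target = masks[:, None].astype(np.float32)
    loss = None
    for w, q in zip(weights, levels):
        if w == 0:
            continue
        term = hybrid_loss_tensor(heads[q], target)
        if w != 1.0:
            term = ad.Tensor(term.data * w, parents=(term,), backward=lambda g, w=w: (g * w,))
        loss = term if loss is None else ad.add(loss, term)
    return loss


def evaluate_loss(net: SegmentationNetwork, data, cfg: TrainConfig) -> float:
    """Total loss on a dataset in eval mode (no gradient graph)."""
    images, masks = _as_arrays(data)
    was_training = net.training
    net.eval()
    try:
        with ad.no_grad():
            total, count = 0.0, 0
            for start in range(0, len(images), cfg.batch_size):
                sl = slice(start, start + cfg.batch_size)
                loss = _batch_loss(net, images[sl], masks[sl], cfg)
                total += float(loss.data) * (sl.indices(len(images))[1] - start)
                count += sl.indices(len(images))[1] - start
    finally:
        if was_training:
            net.train()
    return total / count


def train(net: SegmentationNetwork, train_data, val_data, cfg: TrainConfig):
    """Train in place; returns (net, history).

    history holds per-epoch mean train loss and validation loss, plus the
    index of the restored best epoch.
    """
    images, masks = _as_arrays(train_data)
    if len(images) == 0:
        raise ValueError("training dataset is empty")
    val_images, _ = _as_arrays(val_data)
    if len(val_images) == 0:
        raise ValueError("validation dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(net.parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        net.train()
        order = rng.permutation(len(images))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            optimizer.zero_grad()
            loss = _batch_loss(net, images[idx], masks[idx], cfg)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        history["train_loss"].append(epoch_loss / len(order))
        val_loss = evaluate_loss(net, val_data, cfg)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(net.state_dict())
            history["best_epoch"] = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _predict_proba_map(net: SegmentationNetwork, image: np.ndarray, use_ensemble: bool) -> np.ndarray:
    """(H, W) probability map for one image whose size divides 2^depth."""
    if use_ensemble:
        return ensemble_predict(net, image)[0, 0]
    heads = net.predict_proba(image)
    return heads[max(heads)][0, 0]


def predict_image(
    net: SegmentationNetwork,
    image: np.ndarray,
    patch_spec: Optional[PatchSpec] = None,
    threshold: float = 0.5,
    use_ensemble: Optional[bool] = None,
    batch_size: int = 16,
):
    """Segment a full image; returns (probability map, binary mask).

    Whole-image mode reflect-pads to the required 2^depth divisibility,
    runs the multi-depth ensemble (when several heads are supervised) or
    the single head, and cuts the padding off.  Patch mode reflect-pads
    for full sliding-window coverage, predicts each patch, stitches by
    averaging overlaps, then crops.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("predict_image expects a single-channel HxW image")
    if use_ensemble is None:
        use_ensemble = len(net.head_levels()) > 1
    h, w = image.shape
    if patch_spec is None:
        div = 2 ** net.cfg.depth
        pad_h = (div - h % div) % div
        pad_w = (div - w % div) % div
        padded = np.pad(image, ((0, pad_h), (0, pad_w)), mode="reflect") if (pad_h or pad_w) else image
        prob = _predict_proba_map(net, padded, use_ensemble)[:h, :w]
    else:
        div = 2 ** net.cfg.depth
        if patch_spec.patch_size % div:
            raise ValueError(f"patch size must be divisible by 2^depth = {div}")
        padded, _ = pad_for_full_coverage(image, patch_spec)
        grid = make_grid(padded.shape[0], padded.shape[1], patch_spec)
        patches = [padded[r : r + patch_spec.patch_size, c : c + patch_spec.patch_size] for r, c in grid.origins]
        maps = []
        for start in range(0, len(patches), batch_size):
            batch = np.stack(patches[start : start + batch_size])
            if use_ensemble:
                out = ensemble_predict(net, batch)[:, 0]
            else:
                heads = net.predict_proba(batch)
                out = heads[max(heads)][:, 0]
            maps.extend(out)
        prob = stitch_patches(maps, grid)[:h, :w]
    return prob, binarize(prob, threshold)


# ---------------------------------------------------------------------------
# repeated trials
# ---------------------------------------------------------------------------


def evaluate_on_records(net: SegmentationNetwork, records, threshold: float = 0.5):
    """Whole-image prediction + metrics for every record; list of reports."""
    reports = []
    for rec in records:
        _, pred = predict_image(net, rec.pixels, threshold=threshold)
        reports.append(MetricsReport.from_masks(rec.mask, pred))
    return reports


def run_trials(
    train_cfg: TrainConfig,
    network_cfg: NetworkConfig,
    data_cfg: SyntheticTaskConfig,
    n_trials: int,
    arch: str = "r2upp",
    split_fractions=(0.7, 0.15, 0.15),
    multiscale: bool = False,
) -> TrialSummary:
    """Repeat train/evaluate with fresh weight initializations.

    The dataset and its split are generated once from ``data_cfg`` and held
    fixed; trial ``i`` re-initializes the network and the shuffling stream
    with seed ``train_cfg.seed + i``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ds = generate_multiscale(data_cfg) if multiscale else generate(data_cfg)
    train_ds, val_ds, test_ds = train_val_test_split(ds, split_fractions, seed=data_cfg.seed)
    per_trial, seeds, histories = [], [], []
    for trial in range(n_trials):
        seed = train_cfg.seed + trial
        net = build_baseline(arch, network_cfg, seed=seed)
        net, history = train(net, train_ds, val_ds, replace(train_cfg, seed=seed))
        reports = evaluate_on_records(net, test_ds.records)
        trial_metrics = {
            name: float(np.mean([r.as_dict()[name] for r in reports]))
            for name in MetricsReport.METRIC_NAMES
        }
        per_trial.append(trial_metrics)
        seeds.append(seed)
        histories.append(history)
    aggregate = {}
    for name in MetricsReport.METRIC_NAMES:
        values = np.array([m[name] for m in per_trial])
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        aggregate[name] = {"mean": float(values.mean()), "sd": sd, "n": len(values)}
    return TrialSummary(per_trial=per_trial, aggregate=aggregate, trial_seeds=seeds, histories=histories)
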