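"""Seeded toy segmentation tasks mimicking four biomedical structure regimes.

Styles
------
``membranes``
    Voronoi-tessellated cell interiors (foreground) separated by thin
    dark boundaries, like electron-microscopy neuropil where cells are
    white and membranes black.
``blobs``
    Irregular diffuse regions from a thresholded correlated Gaussian
    random field, like ground-glass lesions in lung CT.
``lobes``
    Two large smooth lobe-shaped regions, like lung fields in a chest
    radiograph.
``vessels``
    Thin curvilinear strokes traced by biased random walks, like retinal
    vasculature.

Images are rendered from the mask (distance-transform shading plus a
1 px Gaussian blur so the image is not trivially thresholdable) and
corrupted with Gaussian noise of standard deviation ``noise_sd``, clipped
to [0, 1].  Every record draws from an independent generator seeded by
``(seed, record index)``, so datasets are bit-reproducible and earlier
records are unaffected when ``n_images`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .patches import ImageRecord

STYLES = ("membranes", "blobs", "lobes", "vessels")

_DEFAULT_FRACTIONS = {
    "membranes": (0.55, 0.97),
    "blobs": (0.08, 0.45),
    "lobes": (0.2, 0.6),
    "vessels": (0.01, 0.2),
}

_MAX_RETRIES = 25


@dataclass(frozen=True)
class SyntheticTaskConfig:
    style: str = "blobs"
    image_size: int = 64
    n_images: int = 20
    object_scale_range: tuple = (0.1, 0.3)
    noise_sd: float = 0.05
    foreground_fraction_range: Optional[tuple] = None  # per-style default when None
    seed: int = 0

    def __post_init__(self):
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}; choose from {STYLES}")
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16 (depth-4 networks)")
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        frange = self.foreground_fraction_range or _DEFAULT_FRACTIONS[self.style]
        frange = (float(frange[0]), float(frange[1]))
        if not (0 < frange[0] < frange[1] < 1):
            raise ValueError("foreground_fraction_range must be ordered within (0, 1)")
        object.__setattr__(self, "foreground_fraction_range", frange)
        srange = (float(self.object_scale_range[0]), float(self.object_scale_range[1]))
        if not (0 < srange[0] <= srange[1] <= 1):
            raise ValueError("object_scale_range must be ordered within (0, 1]")
        object.__setattr__(self, "object_scale_range", srange)


@dataclass
class SyntheticDataset:
    records: list
    config: SyntheticTaskConfig
    foreground_fractions: list = field(default_factory=list)
    object_histograms: list = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def images(self) -> np.ndarray:
        return np.stack([r.pixels for r in self.records])

    def masks(self) -> np.ndarray:
        return np.stack([r.mask for r in self.records])


# ---------------------------------------------------------------------------
# mask generators (one per style)
# ---------------------------------------------------------------------------


def _mask_blobs(cfg: SyntheticTaskConfig, rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    scale = rng.uniform(*cfg.object_scale_range)
    target = rng.uniform(*cfg.foreground_fraction_range)
    # correlated Gaussian field; correlation length sets the blob scale
    field_ = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=max(1.0, scale * size / 2))
    thr = np.quantile(field_, 1.0 - target)
    return (field_ > thr).astype(np.uint8)


def _mask_membranes(cfg: SyntheticTaskConfig, rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    # seed density equivalent to 30-60 cells on a 512x512 canvas
    n_cells = max(5, int(round(rng.uniform(30, 60) * (size / 512) ** 2 + rng.uniform(4, 10))))
    seeds = rng.uniform(0, size, size=(n_cells, 2))
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
    labels = d2.argmin(axis=-1)
    membrane = np.zeros((size, size), dtype=bool)
    membrane[:-1, :] |= labels[:-1, :] != labels[1:, :]
    membrane[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    if rng.random() < 0.5:  # membranes are 1-2 px thick
        membrane = ndimage.binary_dilation(membrane)
    return (~membrane).astype(np.uint8)


def _lobe(size: int, center, semi_axes, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy = (yy - center[0]) / semi_axes[0]
    dx = (xx - center[1]) / semi_axes[1]
    theta = np.arctan2(dy, dx)
    k = rng.integers(2, 5)
    wobble = 1.0 + 0.12 * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return (dy**2 + dx**2) <= wobble


def _mask_lobes(cfg: SyntheticTaskConfig, rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    ry = size * rng.uniform(0.28, 0.4)
    rx = size * rng.uniform(0.15, 0.24)
    cy = size * rng.uniform(0.45, 0.55)
    left = _lobe(size, (cy, size * rng.uniform(0.24, 0.3)), (ry, rx), rng)
    right = _lobe(size, (cy, size * rng.uniform(0.7, 0.76)), (ry, rx), rng)
    return (left | right).astype(np.uint8)


def _trace_walk(canvas: np.ndarray, rng: np.random.Generator, width: float, n_steps: int) -> None:
    size = canvas.shape[0]
    side = rng.integers(4)
    pos = np.array(
        [
            [0.0, rng.uniform(0, size)],
            [size - 1.0, rng.uniform(0, size)],
            [rng.uniform(0, size), 0.0],
            [rng.uniform(0, size), size - 1.0],
        ][side]
    )
    center = np.array([size / 2, size / 2])
    direction = center - pos
    direction /= np.linalg.norm(direction) + 1e-9
    radius = max(0.5, width / 2)
    r_int = int(np.ceil(radius))
    for _ in range(n_steps):
        angle = rng.normal(0, 0.35)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        direction = rot @ direction
        pos = pos + direction
        if not (0 <= pos[0] < size and 0 <= pos[1] < size):
            break
        y0, x0 = int(round(pos[0])), int(round(pos[1]))
        for dy in range(-r_int, r_int + 1):
            for dx in range(-r_int, r_int + 1):
                if dy * dy + dx * dx <= radius * radius:
                    y, x = y0 + dy, x0 + dx
                    if 0 <= y < size and 0 <= x < size:
                        canvas[y, x] = 1


def _mask_vessels(cfg: SyntheticTaskConfig, rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    target = rng.uniform(*cfg.foreground_fraction_range)
    canvas = np.zeros((size, size), dtype=np.uint8)
    for _ in range(200):  # add walks until the target fraction is reached
        width = rng.uniform(1.0, 4.0)
        _trace_walk(canvas, rng, width=width, n_steps=int(size * rng.uniform(0.6, 1.5)))
        if canvas.mean() >= target:
            break
    return canvas


_GENERATORS = {
    "membranes": _mask_membranes,
    "blobs": _mask_blobs,
    "lobes": _mask_lobes,
    "vessels": _mask_vessels,
}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_image(mask: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Mask -> intensity image: distance shading, 1 px blur, Gaussian noise."""
    mask_f = mask.astype(np.float64)
    d_in = ndimage.distance_transform_edt(mask)
    if d_in.max() > 0:
        d_in = d_in / d_in.max()
    base = 0.2 + 0.55 * mask_f + 0.15 * d_in
    base = ndimage.gaussian_filter(base, sigma=1.0)
    if noise_sd > 0:
        base = base + rng.normal(0, noise_sd, size=base.shape)
    return np.clip(base, 0.0, 1.0).astype(np.float32)


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index)])


def generate(cfg: SyntheticTaskConfig) -> SyntheticDataset:
    """Generate ``cfg.n_images`` records; deterministic given (config, seed)."""
    lo, hi = cfg.foreground_fraction_range
    records, fractions = [], []
    for i in range(cfg.n_images):
        rng = _record_rng(cfg.seed, i)
        for attempt in range(_MAX_RETRIES):
            mask = _GENERATORS[cfg.style](cfg, rng)
            frac = float(mask.mean())
            if lo <= frac <= hi:
                break
        else:
            raise ValueError(
                f"could not draw a {cfg.style} mask with foreground fraction in "
                f"[{lo}, {hi}] after {_MAX_RETRIES} attempts (record {i})"
            )
        image = render_image(mask, rng, cfg.noise_sd)
        records.append(ImageRecord(pixels=image, mask=mask, id=f"{cfg.style}-{i:04d}"))
        fractions.append(frac)
    return SyntheticDataset(records=records, config=cfg, foreground_fractions=fractions)


# ---------------------------------------------------------------------------
# multiscale variant
# ---------------------------------------------------------------------------


def _paint_blob(mask: np.ndarray, center, radius: float, rng: np.random.Generator) -> None:
    size = mask.shape[0]
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - center[0], xx - center[1])
    k = rng.integers(3, 6)
    wobble = 1.0 + 0.2 * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    mask[((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= (radius * wobble) ** 2] = 1


def _place_disjoint_blob(mask: np.ndarray, radius: float, rng: np.random.Generator, tries: int = 40) -> bool:
    """Paint one wobbled blob whose dilated footprint avoids existing foreground."""
    size = mask.shape[0]
    reach = int(np.ceil(radius * 1.25)) + 2  # wobble margin + separation gap
    margin = min(reach + 1, size // 2 - 1)
    for _ in range(tries):
        center = rng.uniform(margin, size - margin, size=2)
        y0, x0 = int(center[0]), int(center[1])
        lo_y, hi_y = max(0, y0 - reach), min(size, y0 + reach + 1)
        lo_x, hi_x = max(0, x0 - reach), min(size, x0 + reach + 1)
        if mask[lo_y:hi_y, lo_x:hi_x].sum() == 0:
            _paint_blob(mask, center, radius, rng)
            return True
    return False


def default_scale_bins(scale_range, n_bins: int = 3):
    """Split a scale range into ``n_bins`` disjoint equal-width bins."""
    edges = np.linspace(scale_range[0], scale_range[1], n_bins + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_bins)]


def generate_multiscale(cfg: SyntheticTaskConfig, scale_bins=None) -> SyntheticDataset:
    """Each image carries >= 1 object from every scale bin (blobs/vessels only).

    Object scale is the connected component's bounding-box long side as a
    fraction of the image size; per-record histograms of that measure are
    returned in ``object_histograms``.
    """
    if cfg.style not in ("blobs", "vessels"):
        raise ValueError("multiscale generation supports styles 'blobs' and 'vessels'")
    bins = scale_bins if scale_bins is not None else default_scale_bins(cfg.object_scale_range)
    if len(bins) < 1:
        raise ValueError("need at least one scale bin")
    size = cfg.image_size
    records, fractions, histograms = [], [], []
    for i in range(cfg.n_images):
        rng = _record_rng(cfg.seed, i ^ 0x5CA1E)  # distinct stream from generate()
        for attempt in range(_MAX_RETRIES):
            mask = np.zeros((size, size), dtype=np.uint8)
            placed_all = True
            for lo_s, hi_s in bins:
                scale = rng.uniform(lo_s, hi_s)
                if cfg.style == "blobs":
                    radius = max(1.5, scale * size / 2)
                    placed_all &= _place_disjoint_blob(mask, radius, rng)
                else:
                    sub = np.zeros_like(mask)
                    _trace_walk(sub, rng, width=rng.uniform(1.0, 3.0), n_steps=max(3, int(scale * size)))
                    mask |= sub
            sizes = _component_scales(mask, size)
            if cfg.style == "blobs":
                # painted radii wobble by +/-20%, so the component's box extent
                # lies within [0.8*lo, 1.25*hi] of its bin when nothing merged
                ok = placed_all and len(sizes) == len(bins) and all(
                    any(0.7 * lo_s <= s <= 1.3 * hi_s + 4 / size for s in sizes)
                    for lo_s, hi_s in bins
                )
            else:
                ok = all(any(lo_s - 0.05 <= s <= hi_s + 0.35 for s in sizes) for lo_s, hi_s in bins)
            if ok:
                break
        else:
            raise ValueError(
                f"could not place >=1 disjoint object per scale bin {bins} "
                f"on a {size}x{size} canvas (record {i})"
            )
        image = render_image(mask, rng, cfg.noise_sd)
        records.append(ImageRecord(pixels=image, mask=mask, id=f"{cfg.style}-ms-{i:04d}"))
        fractions.append(float(mask.mean()))
        histograms.append(sorted(_component_scales(mask, size)))
    return SyntheticDataset(
        records=records, config=cfg, foreground_fractions=fractions, object_histograms=histograms
    )


def _component_scales(mask: np.ndarray, size: int):
    labels, n = ndimage.label(mask)
    scales = []
    for sl in ndimage.find_objects(labels):
        extent = max(sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
        scales.append(extent / size)
    return scales


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def train_val_test_split(ds: SyntheticDataset, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Disjoint record-level partition, reproducible from the seed."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(ds.records)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    groups = (order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :])

    def subset(idx):
        return SyntheticDataset(
            records=[ds.records[j] for j in idx],
            config=ds.config,
            foreground_fractions=[ds.foreground_fractions[j] for j in idx] if ds.foreground_fractions else [],
        )

    return tuple(subset(g) for g in groups)
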