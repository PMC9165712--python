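"""Image/mask I/O, cropping, resizing, and the sliding-window patch pipeline.

Coordinate convention is 0-based and half-open everywhere.  Sliding-window
grids use the floor rule, ``positions = floor((dim - patch)/stride) + 1``
per axis with no end-anchored extra window, so strides that do not divide
``dim - patch`` leave an uncovered margin at the bottom/right;
``coverage_report`` quantifies it, and full-image inference reflect-pads
the image so the grid covers every pixel before cutting the pad back off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass(frozen=True)
class PatchSpec:
    patch_size: int
    stride: int

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        if not (1 <= self.stride <= self.patch_size):
            raise ValueError(f"stride must lie in [1, patch_size], got {self.stride}")


@dataclass(frozen=True)
class PatchGrid:
    image_height: int
    image_width: int
    patch_size: int
    stride: int
    rows: int
    cols: int

    @property
    def origins(self):
        """Top-left (row, col) of every patch, row-major."""
        return [
            (r * self.stride, c * self.stride)
            for r in range(self.rows)
            for c in range(self.cols)
        ]

    def __len__(self):
        return self.rows * self.cols


@dataclass
class ImageRecord:
    """An intensity image in [0,1] paired with a binary mask."""

    pixels: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self):
        if self.pixels.shape[:2] != self.mask.shape[:2]:
            raise ValueError(
                f"image {self.id!r}: pixel shape {self.pixels.shape[:2]} != mask shape {self.mask.shape[:2]}"
            )


def crop(image: np.ndarray, row_start: int, row_stop: int, col_start: int, col_stop: int) -> np.ndarray:
    """Half-open sub-image image[row_start:row_stop, col_start:col_stop]."""
    h, w = image.shape[:2]
    if not (0 <= row_start < row_stop <= h and 0 <= col_start < col_stop <= w):
        raise ValueError(
            f"crop bounds rows [{row_start},{row_stop}) cols [{col_start},{col_stop}) "
            f"fall outside a {h}x{w} image"
        )
    return image[row_start:row_stop, col_start:col_stop]


def make_grid(height: int, width: int, spec: PatchSpec) -> PatchGrid:
    """Floor-rule sliding-window grid over a height x width image."""
    if spec.patch_size > min(height, width):
        raise ValueError(
            f"patch size {spec.patch_size} exceeds image extent {height}x{width}"
        )
    rows = (height - spec.patch_size) // spec.stride + 1
    cols = (width - spec.patch_size) // spec.stride + 1
    return PatchGrid(height, width, spec.patch_size, spec.stride, rows, cols)


def coverage_report(grid: PatchGrid) -> dict:
    """Extent covered by the grid and the uncovered bottom/right margins."""
    covered_rows = (grid.rows - 1) * grid.stride + grid.patch_size
    covered_cols = (grid.cols - 1) * grid.stride + grid.patch_size
    return {
        "covered_rows": covered_rows,
        "covered_cols": covered_cols,
        "uncovered_rows": grid.image_height - covered_rows,
        "uncovered_cols": grid.image_width - covered_cols,
    }


def extract_patches(record: ImageRecord, grid: PatchGrid):
    """(image patch, mask patch) pairs in grid (row-major) order."""
    if (grid.image_height, grid.image_width) != record.pixels.shape[:2]:
        raise ValueError(
            f"grid built for {grid.image_height}x{grid.image_width} but record "
            f"{record.id!r} is {record.pixels.shape[0]}x{record.pixels.shape[1]}"
        )
    p = grid.patch_size
    return [
        (record.pixels[r : r + p, c : c + p], record.mask[r : r + p, c : c + p])
        for r, c in grid.origins
    ]


def stitch_patches(patch_maps, grid: PatchGrid, height: int | None = None, width: int | None = None) -> np.ndarray:
    """Average overlapping patch predictions back onto the image plane.

    Pixels no patch covers (floor-rule margins) are left at 0; use
    ``pad_for_full_coverage`` + this + a final crop for gap-free inference.
    """
    patch_maps = list(patch_maps)
    if len(patch_maps) != len(grid):
        raise ValueError(f"got {len(patch_maps)} patch maps for a {len(grid)}-patch grid")
    height = grid.image_height if height is None else height
    width = grid.image_width if width is None else width
    acc = np.zeros((height, width), dtype=np.float64)
    weight = np.zeros((height, width), dtype=np.float64)
    p = grid.patch_size
    for (r, c), patch in zip(grid.origins, patch_maps):
        patch = np.asarray(patch)
        if patch.shape != (p, p):
            raise ValueError(f"patch map shape {patch.shape} != ({p}, {p})")
        acc[r : r + p, c : c + p] += patch
        weight[r : r + p, c : c + p] += 1.0
    out = np.divide(acc, weight, out=np.zeros_like(acc), where=weight > 0)
    return out


def pad_for_full_coverage(image: np.ndarray, spec: PatchSpec):
    """Reflect-pad bottom/right so the floor-rule grid covers every pixel.

    Returns (padded image, (pad_rows, pad_cols)).
    """
    h, w = image.shape[:2]

    def pad_needed(dim):
        if dim < spec.patch_size:
            return spec.patch_size - dim
        rem = (dim - spec.patch_size) % spec.stride
        return (spec.stride - rem) % spec.stride

    pr, pc = pad_needed(h), pad_needed(w)
    pad = [(0, pr), (0, pc)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="reflect"), (pr, pc)


def resize(image: np.ndarray, target_h: int, target_w: int, mode: str = "bilinear") -> np.ndarray:
    """Bilinear resize for intensities, nearest-neighbour for masks."""
    if target_h < 1 or target_w < 1:
        raise ValueError("resize targets must be positive")
    if image.shape[:2] == (target_h, target_w):
        return image.copy()
    if mode == "nearest":
        out = _sk_resize(image, (target_h, target_w), order=0, preserve_range=True, anti_aliasing=False)
        return out.astype(image.dtype)
    if mode == "bilinear":
        return _sk_resize(image, (target_h, target_w), order=1, preserve_range=True, anti_aliasing=False)
    raise ValueError(f"unknown resize mode {mode!r}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_SUPPORTED = {".png", ".tif", ".tiff", ".gif", ".bmp"}


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported image format {path.suffix!r} for {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[0] in (1,) and path.suffix.lower() in (".tif", ".tiff"):
        arr = arr[0]  # single-page multi-frame TIFF
    return arr


def _to_unit_interval(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    arr = arr.astype(np.float32)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def load_record(image_path, mask_path, record_id: str | None = None) -> ImageRecord:
    """Load an image/mask pair; intensities to [0,1], mask nonzero -> 1."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    pixels = _to_unit_interval(_read_image(image_path))
    mask = (_read_image(mask_path) != 0).astype(np.uint8)
    if mask.ndim == 3:
        mask = mask[..., 0]
    if pixels.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image {image_path.name} is {pixels.shape[:2]} but mask {mask_path.name} is {mask.shape[:2]}"
        )
    return ImageRecord(pixels=pixels, mask=mask, id=record_id or image_path.stem)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("save_mask expects a binary {0,1} mask")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def save_image(image: np.ndarray, path) -> None:
    """Write a [0,1] intensity image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))
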