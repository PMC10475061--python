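"""From per-frame disc masks to the classifier-ready clip: find the disc
region, stabilize it across frames, crop, grayscale and resize to the
30-frame 64x64 single-channel contract."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ContractError, DataError
from .io import rgb_to_gray
from .phantom import VideoClip

N_FRAMES = 30
CROP_SIZE = 64
DEFAULT_MARGIN = 0.25


@dataclass(frozen=True)
class BoundingRegion:
    """Half-open pixel region [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def validate(self, height: int | None = None, width: int | None = None) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ContractError(f"degenerate region {self}")
        if self.row_start < 0 or self.col_start < 0:
            raise ContractError(f"negative region start in {self}")
        if height is not None and self.row_end > height:
            raise ContractError(f"region {self} exceeds frame height {height}")
        if width is not None and self.col_end > width:
            raise ContractError(f"region {self} exceeds frame width {width}")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row_start + self.row_end - 1) / 2.0,
                (self.col_start + self.col_end - 1) / 2.0)

    def to_dict(self) -> dict:
        return {"row_start": int(self.row_start), "row_end": int(self.row_end),
                "col_start": int(self.col_start), "col_end": int(self.col_end)}


def _square_pad(r0: int, r1: int, c0: int, c1: int,
                height: int, width: int) -> tuple[int, int, int, int]:
    """Grow the shorter side to the longer one, clamped to frame bounds."""
    side = max(r1 - r0, c1 - c0)

    def grow(lo, hi, limit):
        need = side - (hi - lo)
        lo = lo - need // 2
        hi = hi + (need - need // 2)
        if lo < 0:
            hi = min(hi - lo, limit)
            lo = 0
        elif hi > limit:
            lo = max(lo - (hi - limit), 0)
            hi = limit
        return lo, hi

    r0, r1 = grow(r0, r1, height)
    c0, c1 = grow(c0, c1, width)
    return r0, r1, c0, c1


def mask_to_region(mask: np.ndarray, margin: float = DEFAULT_MARGIN) -> BoundingRegion:
    """Bounding box of the largest 4-connected foreground component,
    expanded by `margin` (a fraction of the box size) per side, clamped,
    and square-padded where the frame allows."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ContractError(f"mask must be 2-D, got shape {mask.shape}")
    if margin < 0:
        raise ContractError("margin must be non-negative")
    fg = mask > 0
    if not fg.any():
        raise DataError("no disc found: mask has no foreground pixels")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n = ndimage.label(fg, structure=structure)
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(labels == largest)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    mr = int(round(margin * (r1 - r0)))
    mc = int(round(margin * (c1 - c0)))
    h, w = mask.shape
    r0, r1 = max(r0 - mr, 0), min(r1 + mr, h)
    c0, c1 = max(c0 - mc, 0), min(c1 + mc, w)
    r0, r1, c0, c1 = _square_pad(r0, r1, c0, c1, h, w)
    return BoundingRegion(r0, r1, c0, c1)


def aggregate_regions(regions: list[BoundingRegion]) -> BoundingRegion:
    """Per-coordinate median across frames, rounded to int (jitter-robust)."""
    if not regions:
        raise DataError("cannot aggregate an empty list of regions")
    coords = np.array([[r.row_start, r.row_end, r.col_start, r.col_end]
                       for r in regions], dtype=float)
    med = np.rint(np.median(coords, axis=0)).astype(int)
    region = BoundingRegion(*med.tolist())
    region.validate()
    return region


def crop_clip(video: VideoClip | np.ndarray, region: BoundingRegion,
              n_frames: int = N_FRAMES, size: int = CROP_SIZE) -> np.ndarray:
    """First `n_frames` frames cropped to `region`, grayscaled, bilinearly
    resized to (size, size) and returned as (n_frames, size, size, 1) floats
    in [0, 1]."""
    frames = video.frames if isinstance(video, VideoClip) else np.asarray(video)
    if frames.ndim not in (3, 4):
        raise ContractError(f"expected (T,H,W[,C]) video, got shape {frames.shape}")
    if frames.shape[0] < n_frames:
        raise ContractError(
            f"video has {frames.shape[0]} frames; classifier needs {n_frames}")
    height, width = frames.shape[1], frames.shape[2]
    region.validate(height, width)
    out = np.empty((n_frames, size, size, 1))
    for t in range(n_frames):
        frame = rgb_to_gray(frames[t])
        patch = frame[region.row_start:region.row_end,
                      region.col_start:region.col_end]
        if patch.shape != (size, size):
            patch = resize(patch, (size, size), order=1, anti_aliasing=False,
                           preserve_range=True)
        out[t, :, :, 0] = patch
    return np.clip(out, 0.0, 1.0)


def regions_from_masks(masks: list[np.ndarray] | np.ndarray,
                       margin: float = DEFAULT_MARGIN) -> list[BoundingRegion]:
    """Per-frame regions, skipping frames whose mask is empty."""
    regions = []
    for mask in masks:
        try:
            regions.append(mask_to_region(mask, margin))
        except DataError:
            continue
    return regions


def center_crop_region(height: int, width: int,
                       size: int | None = None) -> BoundingRegion:
    """Fallback when no disc was found in any frame."""
    side = min(height, width) if size is None else min(size, height, width)
    r0 = (height - side) // 2
    c0 = (width - side) // 2
    return BoundingRegion(r0, r0 + side, c0, c0 + side)
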