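"""Moving-region segmentation by temporal-median background subtraction.

In laboratory tanks the background is nearly static, so the per-pixel median
over the first ``n`` frames is a robust background model: a swimming fish
covers any given pixel for only a minority of those frames.  A frame's moving
regions are the pixels whose absolute difference from the background exceeds
the gray-level threshold ``T_g``; the raw mask is then hole-filled,
despeckled, and median-smoothed, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage


@dataclass
class SegmentationParams:
    """Parameters for background modelling and mask cleaning.

    t_g
        Gray-level threshold on |background - frame| (strict).
    n_background_frames
        Number of initial frames whose per-pixel median forms the background.
    min_blob_area
        Connected components (8-connectivity) smaller than this are removed.
    median_kernel
        Side of the square boolean median filter; odd.
    """

    t_g: float = 75.0
    n_background_frames: int = 100
    min_blob_area: int = 30
    median_kernel: int = 3

    def __post_init__(self) -> None:
        if self.t_g < 0:
            raise ValueError("t_g must be >= 0")
        if self.n_background_frames < 1:
            raise ValueError("n_background_frames must be >= 1")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")


def compute_background(frames: Sequence[np.ndarray], n: int | None = None) -> np.ndarray:
    """Per-pixel median of the first ``n`` frames.

    For even ``n`` the lower of the two middle order statistics is used, so
    the background stays an attainable gray level of the input dtype.
    """
    if len(frames) == 0:
        raise ValueError("no frames given")
    if n is None:
        n = len(frames)
    if n < 1 or n > len(frames):
        raise ValueError(f"n={n} outside [1, {len(frames)}]")
    shape = frames[0].shape
    for f in frames[:n]:
        if f.shape != shape:
            raise ValueError("frames have mismatched shapes")
    stack = np.stack(frames[:n], axis=0)
    # lower median: k-th order statistic with k = (n-1)//2
    k = (n - 1) // 2
    part = np.partition(stack, k, axis=0)
    return part[k]


def segment_frame(frame: np.ndarray, background: np.ndarray, t_g: float) -> np.ndarray:
    """Raw moving-region mask: |background - frame| > t_g (strict)."""
    if frame.shape != background.shape:
        raise ValueError("frame/background shape mismatch")
    diff = np.abs(background.astype(np.int32) - frame.astype(np.int32))
    return diff > t_g


def clean_mask(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Fill interior holes, drop small components, median-smooth.

    The order is fixed: fill -> remove-small -> median.  Hole filling floods
    the background phase from the image border, so foreground components
    touching the border are kept as-is.
    """
    if mask.dtype != bool:
        mask = mask.astype(bool)
    filled = ndimage.binary_fill_holes(mask)
    out = _remove_small(filled, params.min_blob_area)
    if params.median_kernel > 1:
        out = ndimage.median_filter(out.astype(np.uint8), size=params.median_kernel).astype(bool)
    return out


_STRUCT8 = np.ones((3, 3), bool)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]
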