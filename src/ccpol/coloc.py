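"""Object-based two-channel co-localization.

Each channel is segmented to a binary mask; co-localization is the
percentage of pixels of a denominator mask that overlap the other mask.
The same operation quantifies PLA dots at adherens junctions (PLA mask as
query, junction mask as reference) and calcium-switch time courses.

Intensity-correlation coefficients (Manders, Pearson) are deliberately not
provided; the readout here is the pixel-overlap fraction of segmented
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BinaryMaskPair", "segment_mask", "overlap_fraction", "coloc_timecourse"]


@dataclass
class BinaryMaskPair:
    """Same-shape binary masks; A is the query channel, B the reference."""

    mask_a: np.ndarray
    mask_b: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.mask_a)
        b = np.asarray(self.mask_b)
        if a.shape != b.shape:
            raise ValueError("masks must have the same shape")
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise ValueError("masks must be binary")
        self.mask_a = a.astype(bool)
        self.mask_b = b.astype(bool)


def segment_mask(image, method: str = "otsu", min_object_px: int = 9,
                 threshold: float | None = None) -> np.ndarray:
    """Threshold one channel and remove small objects; returns a bool mask.

    ``method`` is 'otsu' (global), 'adaptive' (local mean) or 'manual'
    (requires ``threshold``).  A constant image is degenerate: an empty
    mask is returned with a warning.
    """
    from skimage.filters import threshold_local, threshold_otsu
    from skimage.morphology import remove_small_objects

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D single-channel image")
    if img.max() == img.min():
        warnings.warn("constant image: returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    if method == "otsu":
        mask = img > threshold_otsu(img)
    elif method == "adaptive":
        block = max(3, (min(img.shape) // 8) | 1)
        mask = img > threshold_local(img, block_size=block)
    elif method == "manual":
        if threshold is None:
            raise ValueError("manual method requires a threshold")
        mask = img > threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    if min_object_px > 1:
        # keep objects with >= min_object_px pixels
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return mask


def overlap_fraction(pair: BinaryMaskPair, denominator: str = "query") -> float:
    """Percent of the denominator mask's pixels overlapped by the other mask.

    100 * |A & B| / |D| with D = mask_a ('query', default), mask_b
    ('reference') or their union ('union').  The union mode is symmetric in
    the two channels; the directional modes need not be.
    """
    if denominator == "query":
        denom = pair.mask_a
    elif denominator == "reference":
        denom = pair.mask_b
    elif denominator == "union":
        denom = pair.mask_a | pair.mask_b
    else:
        raise ValueError("denominator must be 'query', 'reference' or 'union'")
    n_denom = int(denom.sum())
    if n_denom == 0:
        raise ValueError("denominator mask is empty")
    n_overlap = int((pair.mask_a & pair.mask_b).sum())
    return 100.0 * n_overlap / n_denom


def coloc_timecourse(image_pairs, timepoints_min, denominator: str = "query",
                     method: str = "otsu", min_object_px: int = 9) -> pd.DataFrame:
    """Overlap percentage vs time with one segmentation setting for the series.

    ``image_pairs`` is a sequence of (channel_a, channel_b) images (or None
    for a missing timepoint, which is flagged, never interpolated).
    """
    if len(image_pairs) < 2:
        raise ValueError("a time course needs at least 2 timepoints")
    if len(image_pairs) != len(timepoints_min):
        raise ValueError("one image pair per timepoint required")
    shapes = {np.asarray(p[0]).shape for p in image_pairs if p is not None}
    if len(shapes) > 1:
        raise ValueError("inconsistent image shapes across the series")
    rows = []
    for t, pair_imgs in zip(timepoints_min, image_pairs):
        if pair_imgs is None:
            rows.append({"time_min": t, "overlap_percent": np.nan,
                         "n_px_a": 0, "n_px_b": 0, "n_overlap": 0,
                         "flag": "missing"})
            continue
        a = segment_mask(pair_imgs[0], method=method, min_object_px=min_object_px)
        b = segment_mask(pair_imgs[1], method=method, min_object_px=min_object_px)
        pair = BinaryMaskPair(a, b)
        try:
            pct = overlap_fraction(pair, denominator=denominator)
            flag = ""
        except ValueError:
            pct, flag = np.nan, "empty_denominator"
        rows.append({"time_min": t, "overlap_percent": pct,
                     "n_px_a": int(a.sum()), "n_px_b": int(b.sum()),
                     "n_overlap": int((a & b).sum()), "flag": flag})
    return pd.DataFrame(rows)
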