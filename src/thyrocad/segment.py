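"""Global-threshold binarization and nodule localization.

The filtered image is reduced to a binary mask with a single global
threshold — either a fixed intensity or Otsu's threshold, the maximizer of
between-class variance over the 256-bin histogram.  Thyroid nodules are
hypoechoic (darker than surrounding parenchyma), so the nodule is sought
among the below-threshold (0) regions: the largest 4-connected dark
component that does not touch the image border.  Border-touching components
are excluded first because the anechoic rim and the dark sector edges of a
fan-beam image otherwise dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentConfig",
    "NoduleROI",
    "SegmentationError",
    "otsu_threshold",
    "binarize",
    "locate_nodule",
    "crop_roi",
]

# 4-connectivity: avoids diagonal leakage through speckle.
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class SegmentationError(RuntimeError):
    """No plausible nodule component was found in the binary mask."""


@dataclass
class SegmentConfig:
    """Thresholding mode and ROI acceptance parameters.

    ``threshold_mode`` is ``"otsu"`` (parameter-free, default) or ``"fixed"``
    with an explicit ``fixed_threshold`` intensity.  Dark components smaller
    than ``min_roi_area`` pixels are rejected as speckle artifacts.
    """

    threshold_mode: str = "otsu"
    fixed_threshold: Optional[int] = None
    min_roi_area: int = 25

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"threshold_mode must be 'otsu' or 'fixed', got {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_mode requires fixed_threshold")
        if self.fixed_threshold is not None and not 0 <= self.fixed_threshold <= 255:
            raise ValueError("fixed_threshold must lie in [0, 255]")


@dataclass
class NoduleROI:
    """A localized nodule candidate: mask (1 = nodule), tight bbox, area.

    ``bbox`` is half-open (row0, col0, row1, col1) in image coordinates.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area: int


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's global threshold on the 256-bin histogram.

    Returns the intensity t maximizing the between-class variance of the
    split {v < t} / {v >= t}; ties break toward the lowest t.  A constant
    image has no valid split and returns 0 (everything maps to one class).
    """
    arr = np.asarray(image)
    hist = np.bincount(arr.ravel().astype(np.int64), minlength=256).astype(np.float64)
    total = hist.sum()
    if total == 0:
        raise ValueError("empty image")
    prob = hist / total
    levels = np.arange(256)
    # For threshold t, class 0 holds levels 0..t-1.
    w0 = np.cumsum(prob)[:-1]            # w0[t-1] for t = 1..255
    w1 = 1.0 - w0
    cum_mean = np.cumsum(prob * levels)[:-1]
    grand_mean = float((prob * levels).sum())
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand_mean - cum_mean) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~valid] = -np.inf
    return int(np.argmax(var_between)) + 1


def binarize(image: np.ndarray, config: SegmentConfig | None = None) -> np.ndarray:
    """Binarize with a single global threshold: pixel >= t -> 1, else 0."""
    config = config or SegmentConfig()
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if config.threshold_mode == "fixed":
        t = int(config.fixed_threshold)  # type: ignore[arg-type]
    else:
        t = otsu_threshold(arr)
    return (arr >= t).astype(np.uint8)


def _component_roi(labels: np.ndarray, component: int) -> NoduleROI:
    mask = (labels == component).astype(np.uint8)
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    return NoduleROI(mask=mask, bbox=bbox, area=int(mask.sum()))


def locate_nodule(mask: np.ndarray, config: SegmentConfig | None = None) -> NoduleROI:
    """Locate the nodule among the dark (0) regions of a binary mask.

    Preference order: the largest 4-connected 0-component of area >=
    ``min_roi_area`` that does not touch the image border; failing that, the
    largest 0-component of sufficient area regardless of border contact.
    Raises :class:`SegmentationError` when no dark component is large enough.
    """
    config = config or SegmentConfig()
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    labels, n = ndimage.label(arr == 0, structure=_STRUCTURE_4)
    if n == 0:
        raise SegmentationError("no dark (0) region in mask")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    border = np.zeros(arr.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touches = np.zeros(n + 1, dtype=bool)
    touches[np.unique(labels[border])] = True

    big = areas >= config.min_roi_area
    interior = big & ~touches[1:]
    if interior.any():
        pick = int(np.flatnonzero(interior)[np.argmax(areas[interior])]) + 1
        return _component_roi(labels, pick)
    if big.any():
        pick = int(np.flatnonzero(big)[np.argmax(areas[big])]) + 1
        return _component_roi(labels, pick)
    raise SegmentationError(
        f"no dark component of area >= {config.min_roi_area} pixels "
        f"(largest found: {int(areas.max())})"
    )


def crop_roi(image: np.ndarray, roi: NoduleROI, margin: int = 0) -> np.ndarray:
    """Extract the ROI bounding box expanded by ``margin``, clipped to bounds."""
    arr = np.asarray(image)
    r0, c0, r1, c1 = roi.bbox
    r0 = max(0, r0 - margin)
    c0 = max(0, c0 - margin)
    r1 = min(arr.shape[0], r1 + margin)
    c1 = min(arr.shape[1], c1 + margin)
    return arr[r0:r1, c0:c1]
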