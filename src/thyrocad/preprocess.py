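"""Geometry normalization and impulse-noise removal.

Every image is first resized to a common working geometry (256 x 256 by
default) with bilinear interpolation, then passed through a square median
filter with zero padding.  The median filter is the standard remedy for the
salt-and-pepper impulse noise typical of digitized ultrasound stills: it
replaces each pixel with the median of its k x k neighborhood, so isolated
extreme pixels vanish while edges survive.  Zero padding darkens a one-pixel
border (most visibly the corners, whose neighborhoods are majority padding);
this artifact is a deliberate part of the pipeline's definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

__all__ = ["PreprocessConfig", "resize", "median_filter", "preprocess"]


@dataclass
class PreprocessConfig:
    """Working geometry and filter kernel.

    ``target_size`` is (rows, cols); ``kernel_size`` must be odd and >= 3 so
    the neighborhood count is odd and the median is a single order statistic.
    Padding is fixed to zeros.
    """

    target_size: tuple[int, int] = (256, 256)
    kernel_size: int = 3

    def __post_init__(self) -> None:
        _check_kernel(self.kernel_size)
        if min(self.target_size) < self.kernel_size:
            raise ValueError("target dimensions must be >= kernel_size")


def _check_kernel(kernel_size: int) -> None:
    if kernel_size % 2 == 0 or kernel_size < 3:
        raise ValueError(f"kernel_size must be odd and >= 3, got {kernel_size}")


def resize(image: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Resize to ``target_size`` (rows, cols) with bilinear interpolation.

    Output values are rounded and clamped to [0, 255]; a same-size call is
    the identity on 8-bit input.
    """
    rows, cols = int(target_size[0]), int(target_size[1])
    if rows < 1 or cols < 1:
        raise ValueError(f"target size must be positive, got {target_size}")
    arr = np.asarray(image, dtype=np.float64)
    if arr.shape == (rows, cols):
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    out = _skimage_resize(arr, (rows, cols), order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def median_filter(image: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Median filter with a zero-padded square kernel.

    Each output pixel is the median of the kernel_size x kernel_size
    neighborhood of its input, with out-of-bounds positions read as 0.
    """
    _check_kernel(kernel_size)
    arr = np.asarray(image, dtype=np.uint8)
    return ndimage.median_filter(arr, size=kernel_size, mode="constant", cval=0)


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Resize then median-filter, the pipeline's canonical order."""
    config = config or PreprocessConfig()
    return median_filter(resize(image, config.target_size), config.kernel_size)
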