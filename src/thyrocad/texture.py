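"""Gray-level co-occurrence matrix (GLCM) texture features.

The GLCM of a quantized image at offset (distance d, angle theta) is the
normalized joint distribution p(i, j) of gray-level pairs separated by that
offset.  From it the seven classical second-order (Haralick-style) features
are computed:

    energy        sum p(i,j)^2
    correlation   sum (i - mu_i)(j - mu_j) p(i,j) / (sigma_i sigma_j)
    entropy       -sum p(i,j) log2 p(i,j)           (0 log 0 := 0)
    homogeneity   sum p(i,j) / (1 + |i - j|)
    cluster shade sum (i + j - mu_x - mu_y)^3 p(i,j)
    contrast      sum (i - j)^2 p(i,j)
    IDM           sum p(i,j) / (1 + (i - j)^2)      (inverse difference moment)

mu_i, sigma_i are the mean/sd of the row marginal p_x (and mu_x = mu_i by
construction; likewise for columns).  Homogeneity and IDM differ only in
their penalty on off-diagonal mass (linear vs quadratic); both are 1 exactly
when the matrix is diagonal.  When sigma_i * sigma_j = 0 the distribution is
a delta in at least one marginal and correlation is defined as 1.

Angles follow the common convention: 0 deg pairs each pixel with the one d
columns to its right, 90 deg with the one d rows above, 45/135 deg with the
upper-right/upper-left diagonals.  In symmetric mode each pair is counted in
both orders, making p equal to its transpose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .segment import NoduleROI, crop_roi

__all__ = [
    "FEATURE_NAMES",
    "GLCMConfig",
    "GLCMatrix",
    "TextureFeatures",
    "quantize",
    "glcm",
    "features",
    "extract",
]

FEATURE_NAMES = (
    "energy",
    "correlation",
    "entropy",
    "homogeneity",
    "cluster_shade",
    "contrast",
    "idm",
)

#: angle (degrees) -> (row, col) displacement unit
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMConfig:
    """Quantization depth, offsets and aggregation for feature extraction."""

    levels: int = 8
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    averaged: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        bad = set(self.angles) - set(_ANGLE_OFFSETS)
        if bad:
            raise ValueError(f"angles must be within {sorted(_ANGLE_OFFSETS)}, got {sorted(bad)}")


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence probabilities with marginal moments."""

    p: np.ndarray
    levels: int

    @property
    def px(self) -> np.ndarray:
        """Row marginal p_x(i) = sum_j p(i, j)."""
        return self.p.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        """Column marginal p_y(j) = sum_i p(i, j)."""
        return self.p.sum(axis=0)

    @property
    def mu_i(self) -> float:
        return float(np.arange(self.levels) @ self.px)

    @property
    def mu_j(self) -> float:
        return float(np.arange(self.levels) @ self.py)

    @property
    def sigma_i(self) -> float:
        i = np.arange(self.levels)
        return float(math.sqrt(max(0.0, (i - self.mu_i) ** 2 @ self.px)))

    @property
    def sigma_j(self) -> float:
        j = np.arange(self.levels)
        return float(math.sqrt(max(0.0, (j - self.mu_j) ** 2 @ self.py)))


@dataclass
class TextureFeatures:
    """The seven-element GLCM feature vector."""

    energy: float
    correlation: float
    entropy: float
    homogeneity: float
    cluster_shade: float
    contrast: float
    idm: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "TextureFeatures":
        return cls(**dict(zip(FEATURE_NAMES, map(float, values))))


def quantize(image: np.ndarray, levels: int = 8) -> np.ndarray:
    """Min-max linear binning of an image onto gray levels 0..levels-1.

    Binning uses the image's own intensity range; a constant image maps
    entirely to level 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    arr = np.asarray(image, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.intp)
    q = np.floor((arr - lo) * levels / (hi - lo)).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(
    quantized: np.ndarray,
    levels: int,
    distance: int = 1,
    angle: int = 0,
    symmetric: bool = True,
) -> GLCMatrix:
    """Build the normalized co-occurrence matrix for one (distance, angle).

    Counts ordered pixel pairs (reference, neighbor) separated by the offset;
    in symmetric mode the transpose is added before normalization.
    """
    arr = np.asarray(quantized)
    if arr.max(initial=0) >= levels:
        raise ValueError("quantized values must be < levels")
    try:
        dr, dc = _ANGLE_OFFSETS[angle]
    except KeyError:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}") from None
    dr, dc = dr * distance, dc * distance
    h, w = arr.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"image {arr.shape} too small for offset ({dr}, {dc})")

    # Reference window and its displaced neighbor window.
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    ref = arr[r0:r1, c0:c1].ravel()
    nbr = arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(ref * levels + nbr, minlength=levels * levels).astype(np.float64)
    counts = counts.reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for this offset")
    return GLCMatrix(p=counts / total, levels=levels)


def features(matrix: GLCMatrix) -> TextureFeatures:
    """Compute the seven texture features from a normalized GLCM."""
    p = matrix.p
    n = matrix.levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]

    energy = float((p ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())

    mu_i, mu_j = matrix.mu_i, matrix.mu_j
    sigma_i, sigma_j = matrix.sigma_i, matrix.sigma_j
    if sigma_i * sigma_j == 0:
        correlation = 1.0  # delta marginal: perfectly (degenerately) correlated
    else:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum()) / (sigma_i * sigma_j))
    cluster_shade = float((((i + j - mu_i - mu_j) ** 3) * p).sum())

    return TextureFeatures(
        energy=energy,
        correlation=correlation,
        entropy=entropy,
        homogeneity=homogeneity,
        cluster_shade=cluster_shade,
        contrast=contrast,
        idm=idm,
    )


def extract(
    image: np.ndarray,
    roi: Optional[NoduleROI] = None,
    config: GLCMConfig | None = None,
    margin: int = 0,
) -> TextureFeatures:
    """Quantize, build GLCMs over all configured offsets and aggregate.

    With a ROI the features are computed on its (margin-expanded) bounding-box
    crop; without one, on the full raster.  In averaged mode (default) each
    feature is the mean over all (distance, angle) combinations; otherwise the
    first configured combination is used alone.
    """
    config = config or GLCMConfig()
    target = crop_roi(image, roi, margin) if roi is not None else np.asarray(image)
    q = quantize(target, config.levels)
    combos = [(d, a) for d in config.distances for a in config.angles]
    if not config.averaged:
        combos = combos[:1]
    vectors = [
        features(glcm(q, config.levels, distance=d, angle=a, symmetric=config.symmetric)).as_array()
        for d, a in combos
    ]
    return TextureFeatures.from_array(np.mean(vectors, axis=0))
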