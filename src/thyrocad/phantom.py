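"""Synthetic ultrasound nodule phantoms with ground truth.

Each phantom is a speckled grayscale image containing one dark (hypoechoic)
elliptical nodule on a brighter parenchyma background.  Benign nodules are
smooth ellipses with homogeneous interiors; malignant nodules carry the
classic suspicion descriptors — an irregular margin (a smooth random periodic
perturbation of the boundary radius), marked hypoechogenicity (lower mean),
internal heterogeneity (a smooth random intensity field) and punctate bright
microcalcifications.  The image is then degraded by multiplicative unit-mean
speckle (a first-order stand-in for B-mode interference noise) and
salt-and-pepper impulse noise, mimicking a digitized ultrasound still.

Every case carries its noiseless ground-truth nodule mask, a synthesized
TI-RADS category consistent with the label, and the realized generation
parameters, so segmentation, texture and classification can all be validated
without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import BENIGN, MALIGNANT, CaseMetadata, write_case_xml, write_image

__all__ = ["PhantomConfig", "PhantomCase", "generate_case", "generate_cases", "generate_dataset"]


@dataclass
class PhantomConfig:
    """Generation parameters; the defaults define the study conditions.

    Intensities are 8-bit gray levels.  ``speckle_scale`` is the standard
    deviation of the unit-mean multiplicative noise; ``impulse_density`` the
    fraction of pixels replaced by salt (255) or pepper (0);
    ``margin_irregularity`` the total radial perturbation amplitude as a
    fraction of the nodule radius (applied to malignant cases only);
    ``heterogeneity_*`` the within-nodule intensity sd of the internal
    texture field, whose spatial correlation length is ``heterogeneity_grain``
    (Gaussian smoothing sigma in pixels; ~1 px keeps the roughness visible to
    distance-1 co-occurrence statistics).  ``benign_fraction`` defaults to 1/3, reproducing a 33:66
    benign:malignant class balance at 99 cases.
    """

    image_size: tuple[int, int] = (256, 256)
    n_cases: int = 99
    benign_fraction: float = 1.0 / 3.0
    background_mean: float = 140.0
    nodule_mean_benign: float = 60.0
    nodule_mean_malignant: float = 45.0
    speckle_scale: float = 0.25
    impulse_density: float = 0.02
    margin_irregularity: float = 0.35
    heterogeneity_benign: float = 4.0
    heterogeneity_malignant: float = 35.0
    heterogeneity_grain: float = 1.0
    n_calcifications: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.benign_fraction <= 1.0:
            raise ValueError("benign_fraction must lie in [0, 1]")
        if not 0.0 <= self.impulse_density < 0.5:
            raise ValueError("impulse_density must lie in [0, 0.5)")
        if self.margin_irregularity < 0 or self.speckle_scale < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class PhantomCase:
    """One synthetic case: image, truth mask, label, metadata, parameters."""

    case_id: str
    image: np.ndarray
    truth_mask: np.ndarray
    label: str
    metadata: CaseMetadata
    params: dict = field(default_factory=dict)


def _boundary_profile(rng: np.random.Generator, amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth periodic radius perturbation: coefficients for cos/sin."""
    harmonics = np.arange(2, 7)
    raw = rng.normal(size=(2, harmonics.size))
    norm = np.abs(raw).sum()
    coef = raw * (amplitude / norm) if norm > 0 else raw * 0.0
    return harmonics, coef


def _nodule_geometry(rng: np.random.Generator, shape: tuple[int, int],
                     irregular: bool, amplitude: float, retries: int = 50):
    """Sample center/axes/rotation so the perturbed boundary stays in bounds."""
    h, w = shape
    for _ in range(retries):
        a = rng.uniform(0.10, 0.20) * h   # semi-axis along rows
        b = rng.uniform(0.10, 0.20) * w   # semi-axis along cols
        theta = rng.uniform(0.0, math.pi)
        reach = max(a, b) * (1.0 + (amplitude if irregular else 0.0)) + 4.0
        if 2 * reach >= min(h, w):
            continue
        cy = rng.uniform(reach, h - reach)
        cx = rng.uniform(reach, w - reach)
        return cy, cx, a, b, theta
    raise RuntimeError("could not place a nodule inside the image bounds")


def generate_case(config: PhantomConfig, label: str,
                  rng: np.random.Generator, case_id: str = "case") -> PhantomCase:
    """Generate one phantom with the given label.

    Pipeline: constant background; dark ellipse (perturbed boundary,
    heterogeneity field and microcalcifications when malignant);
    multiplicative unit-mean speckle; salt-and-pepper impulses; clamp to
    [0, 255].  The truth mask is the noiseless interior of the realized
    boundary.
    """
    if label not in (BENIGN, MALIGNANT):
        raise ValueError(f"label must be {BENIGN!r} or {MALIGNANT!r}")
    malignant = label == MALIGNANT
    h, w = config.image_size

    cy, cx, a, b, theta = _nodule_geometry(
        rng, (h, w), malignant, config.margin_irregularity
    )
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = rows - cy, cols - cx
    u = dy * math.cos(theta) + dx * math.sin(theta)
    v = -dy * math.sin(theta) + dx * math.cos(theta)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)

    if malignant and config.margin_irregularity > 0:
        phi = np.arctan2(v / b, u / a)
        harmonics, coef = _boundary_profile(rng, config.margin_irregularity)
        k_phi = np.multiply.outer(harmonics, phi)
        wobble = np.tensordot(coef[0], np.cos(k_phi), axes=1) + np.tensordot(coef[1], np.sin(k_phi), axes=1)
        boundary = np.maximum(1.0 + wobble, 0.3)
    else:
        boundary = np.ones_like(rho)
    inside = rho <= boundary
    truth_mask = inside.astype(np.uint8)

    img = np.full((h, w), config.background_mean, dtype=np.float64)
    nodule_mean = config.nodule_mean_malignant if malignant else config.nodule_mean_benign
    img[inside] = nodule_mean

    hetero = config.heterogeneity_malignant if malignant else config.heterogeneity_benign
    if hetero > 0:
        field_raw = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=config.heterogeneity_grain)
        sd = field_raw.std()
        if sd > 0:
            img[inside] += (field_raw[inside] / sd) * hetero

    n_calc = config.n_calcifications if malignant else 0
    core = np.flatnonzero((rho <= 0.7 * boundary).ravel())
    if n_calc > 0 and core.size > 0:
        centers = rng.choice(core, size=min(n_calc, core.size), replace=False)
        for flat in centers:
            r, c = divmod(int(flat), w)
            rr = slice(max(0, r - 1), min(h, r + 2))
            cc = slice(max(0, c - 1), min(w, c + 2))
            spot = np.sqrt((np.arange(rr.start, rr.stop)[:, None] - r) ** 2
                           + (np.arange(cc.start, cc.stop)[None, :] - c) ** 2) <= 1.2
            img[rr, cc][spot] = 235.0

    if config.speckle_scale > 0:
        s2 = config.speckle_scale ** 2
        img *= rng.gamma(shape=1.0 / s2, scale=s2, size=(h, w))

    if config.impulse_density > 0:
        hit = rng.random((h, w)) < config.impulse_density
        salt = rng.random((h, w)) < 0.5
        img[hit & salt] = 255.0
        img[hit & ~salt] = 0.0

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    tirads = str(rng.choice(["2", "3"] if not malignant else ["4a", "4b", "4c", "5"]))
    metadata = CaseMetadata(
        case_id=case_id,
        age=int(rng.integers(20, 81)),
        sex=str(rng.choice(["F", "M"])),
        composition="solid",
        shape="taller-than-wide" if malignant else "oval",
        margin="irregular" if malignant else "smooth",
        calcifications="microcalcifications" if malignant else "none",
        tirads=tirads,
        diagnosis=label,
    )
    params = {
        "center": (float(cy), float(cx)),
        "semi_axes": (float(a), float(b)),
        "rotation_rad": float(theta),
        "nodule_mean": float(nodule_mean),
        "heterogeneity_sd": float(hetero),
        "n_calcifications": int(n_calc),
        "speckle_scale": float(config.speckle_scale),
        "impulse_density": float(config.impulse_density),
    }
    return PhantomCase(case_id=case_id, image=image, truth_mask=truth_mask,
                       label=label, metadata=metadata, params=params)


def _label_sequence(config: PhantomConfig, rng: np.random.Generator) -> list[str]:
    n_benign = int(round(config.n_cases * config.benign_fraction))
    labels = [BENIGN] * n_benign + [MALIGNANT] * (config.n_cases - n_benign)
    rng.shuffle(labels)
    return labels


def generate_cases(config: PhantomConfig | None = None) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms in memory, deterministic under seed."""
    config = config or PhantomConfig()
    if config.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(config.seed)
    labels = _label_sequence(config, rng)
    width = max(4, len(str(config.n_cases)))
    return [
        generate_case(config, label, rng, case_id=f"case_{idx:0{width}d}")
        for idx, label in enumerate(labels, start=1)
    ]


def generate_dataset(config: PhantomConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate phantoms and write the on-disk dataset layout.

    Layout: ``images/*.png``, ``masks/*.png`` (0/255), ``xml/*.xml`` and a
    ``manifest.csv`` with one row per case.  Returns the manifest frame.
    """
    out = Path(out_dir)
    for sub in ("images", "masks", "xml"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cases = generate_cases(config)
    rows = []
    for case in cases:
        write_image(out / "images" / f"{case.case_id}.png", case.image)
        write_image(out / "masks" / f"{case.case_id}.png", case.truth_mask * 255)
        write_case_xml(out / "xml" / f"{case.case_id}.xml", case.metadata)
        rows.append({
            "case_id": case.case_id,
            "label": case.label,
            "tirads": case.metadata.tirads,
            "image": f"images/{case.case_id}.png",
            "mask": f"masks/{case.case_id}.png",
            "xml": f"xml/{case.case_id}.xml",
        })
    manifest = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
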