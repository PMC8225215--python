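"""Textual per-case diagnostic report.

The report summarizes what a reading clinician needs at a glance: nodule
composition, echogenicity, margin character, the classifier's call with its
score, a suspicion level, and whether a fine-needle aspirate biopsy (FNAB)
is recommended — FNAB is recommended exactly when the call is malignant.

Descriptor rules when no expert metadata is available:

* echogenicity — ratio of mean ROI intensity to mean background intensity:
  < 0.8 hypoechoic, 0.8-1.2 isoechoic, > 1.2 hyperechoic;
* margin — boundary roughness via the isoperimetric compactness
  perimeter^2 / (4 pi area) of the ROI mask: > 1.5 irregular, else smooth;
* composition — "solid" (the phantom generator emulates solid nodules).

The suspicion level ("type") is a quartile band of the model's probability
score (SVM margins are first mapped through a logistic function).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from skimage.measure import perimeter as _mask_perimeter

from .data_io import CaseMetadata, MALIGNANT
from .segment import NoduleROI
from .texture import FEATURE_NAMES, TextureFeatures

__all__ = ["CaseReport", "build_report", "format_report"]

_SUSPICION_BANDS = (
    (0.25, "low suspicion"),
    (0.50, "intermediate suspicion"),
    (0.75, "moderate suspicion"),
    (1.01, "high suspicion"),
)


@dataclass
class CaseReport:
    """One case's human-facing summary; every field is always populated."""

    case_id: str
    composition: str
    echogenicity: str
    margin: str
    classification: str
    type: str
    recommend_fnab: bool
    score: float
    feature_values: TextureFeatures

    def as_dict(self) -> dict:
        out = asdict(self)
        out["feature_values"] = dict(zip(FEATURE_NAMES, self.feature_values.as_array()))
        return out


def _echogenicity(image: np.ndarray, roi: NoduleROI) -> str:
    inside = roi.mask.astype(bool)
    outside = ~inside
    if not outside.any() or not inside.any():
        return "isoechoic"
    background = float(np.asarray(image, dtype=np.float64)[outside].mean())
    if background == 0:
        return "hyperechoic"
    ratio = float(np.asarray(image, dtype=np.float64)[inside].mean()) / background
    if ratio < 0.8:
        return "hypoechoic"
    if ratio <= 1.2:
        return "isoechoic"
    return "hyperechoic"


def _margin(roi: NoduleROI) -> str:
    area = float(roi.area)
    if area <= 0:
        return "smooth-margin"
    perim = float(_mask_perimeter(roi.mask.astype(bool), neighborhood=4))
    compactness = perim ** 2 / (4.0 * math.pi * area)
    return "irregular" if compactness > 1.5 else "smooth-margin"


def _probability(score: float, kind: str) -> float:
    if kind == "svm":
        return 1.0 / (1.0 + math.exp(-score))
    return float(score)


def _suspicion(prob: float) -> str:
    for upper, name in _SUSPICION_BANDS:
        if prob < upper:
            return name
    return _SUSPICION_BANDS[-1][1]


def build_report(
    case_id: str,
    image: np.ndarray,
    prediction_label: str,
    prediction_score: float,
    features: TextureFeatures,
    roi: NoduleROI | None = None,
    metadata: CaseMetadata | None = None,
    model_kind: str = "svm",
) -> CaseReport:
    """Assemble the case report.

    Descriptors are echoed from expert metadata when present; otherwise they
    are derived from the image and ROI by the documented rules.  FNAB is
    recommended iff the classification is malignant.
    """
    composition = (metadata.composition if metadata and metadata.composition else "solid")
    if metadata and metadata.margin:
        margin = metadata.margin
    elif roi is not None:
        margin = _margin(roi)
    else:
        margin = "indeterminate"
    if roi is not None:
        echogenicity = _echogenicity(image, roi)
    else:
        echogenicity = "indeterminate"

    malignant = prediction_label == MALIGNANT
    prob = _probability(prediction_score, model_kind)
    return CaseReport(
        case_id=case_id or "unknown",
        composition=composition,
        echogenicity=echogenicity,
        margin=margin,
        classification=prediction_label,
        type=_suspicion(prob),
        recommend_fnab=malignant,
        score=float(prediction_score),
        feature_values=features,
    )


def format_report(report: CaseReport) -> str:
    """Aligned plain-text rendering of a case report."""
    lines = [
        f"Case:            {report.case_id}",
        f"Composition:     {report.composition}",
        f"Echogenicity:    {report.echogenicity}",
        f"Margin:          {report.margin}",
        f"Classification:  {report.classification}",
        f"Type:            {report.type}",
        f"Score:           {report.score:.4f}",
        f"FNAB advised:    {'yes' if report.recommend_fnab else 'no'}",
        "Texture features:",
    ]
    values = report.feature_values.as_array()
    for name, value in zip(FEATURE_NAMES, values):
        lines.append(f"  {name:<14} {value: .6f}")
    return "\n".join(lines)
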