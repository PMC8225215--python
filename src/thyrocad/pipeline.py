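"""End-to-end orchestration: images -> features -> classifier -> report.

One call chains the stages in their canonical order (resize, median filter,
binarize, nodule localization, GLCM features, split, standardize, train,
predict, evaluate) with the configuration objects of the individual modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluate as ev
from .data_io import Dataset
from .model import (MLPConfig, SplitSpec, TrainedModel, predict, split,
                    standardize, train_ann, train_svm)
from .preprocess import PreprocessConfig, preprocess
from .segment import NoduleROI, SegmentConfig, SegmentationError, binarize, locate_nodule
from .texture import FEATURE_NAMES, GLCMConfig, TextureFeatures, extract

__all__ = ["CaseResult", "analyze_image", "feature_table", "train_and_evaluate", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass
class CaseResult:
    """Per-image preprocessing/segmentation/texture outcome."""

    case_id: str
    filtered: np.ndarray
    mask: np.ndarray
    roi: Optional[NoduleROI]
    features: TextureFeatures
    roi_fallback: bool  # True when segmentation failed and the whole image was used


def analyze_image(
    image: np.ndarray,
    case_id: str = "",
    pre_config: PreprocessConfig | None = None,
    seg_config: SegmentConfig | None = None,
    glcm_config: GLCMConfig | None = None,
    roi_margin: int = 2,
) -> CaseResult:
    """Run one image through preprocessing, segmentation and texture.

    When no nodule component is found the features fall back to the whole
    image and a warning is logged.
    """
    filtered = preprocess(image, pre_config)
    seg_config = seg_config or SegmentConfig()
    mask = binarize(filtered, seg_config)
    roi: Optional[NoduleROI]
    fallback = False
    try:
        roi = locate_nodule(mask, seg_config)
    except SegmentationError as exc:
        logger.warning("case %s: %s; falling back to whole-image features", case_id, exc)
        roi = None
        fallback = True
    feats = extract(filtered, roi=roi, config=glcm_config, margin=roi_margin)
    return CaseResult(case_id=case_id, filtered=filtered, mask=mask, roi=roi,
                      features=feats, roi_fallback=fallback)


def feature_table(
    dataset: Dataset,
    pre_config: PreprocessConfig | None = None,
    seg_config: SegmentConfig | None = None,
    glcm_config: GLCMConfig | None = None,
    roi_margin: int = 2,
) -> tuple[pd.DataFrame, list[CaseResult]]:
    """Texture-feature table (case_id, label, seven features) for a dataset."""
    rows = []
    results = []
    for case in dataset:
        result = analyze_image(case.image, case.case_id, pre_config, seg_config,
                               glcm_config, roi_margin)
        results.append(result)
        row = {"case_id": case.case_id, "label": case.label}
        row.update(dict(zip(FEATURE_NAMES, result.features.as_array())))
        rows.append(row)
    return pd.DataFrame(rows), results


@dataclass
class PipelineResult:
    """Outcome of one train/evaluate run on a feature table."""

    model: TrainedModel
    train: pd.DataFrame
    test: pd.DataFrame
    predictions: pd.DataFrame
    report: ev.PerformanceReport


def train_and_evaluate(
    features: pd.DataFrame,
    classifier: str = "svm",
    split_spec: SplitSpec | None = None,
    mlp_config: MLPConfig | None = None,
    svm_kernel: str = "rbf",
    svm_c: float = 1.0,
) -> PipelineResult:
    """Split a feature table, fit one classifier, evaluate on the test side.

    The scaler is fitted on the training split only.  The report carries the
    confusion-matrix metrics at the model's default decision threshold plus
    AUROC and the ROC operating point when the test side has both classes.
    """
    train, test = split(features, split_spec)
    train_scaled, scaler = standardize(train)
    if classifier == "ann":
        model = train_ann(train_scaled, mlp_config, scaler=scaler)
    elif classifier == "svm":
        model = train_svm(train_scaled, kernel=svm_kernel, C=svm_c, scaler=scaler)
    else:
        raise ValueError(f"classifier must be 'ann' or 'svm', got {classifier!r}")

    predictions = predict(model, test)
    cm = ev.confusion(predictions["label"], test["label"])
    report = ev.metrics(cm)
    truth = test["label"].to_numpy()
    if len(set(truth)) == 2:
        curve = ev.roc(predictions["score"].to_numpy(), truth)
        report.auroc = curve.auroc
        report.threshold, report.roc_distance = ev.operating_point(curve)
    return PipelineResult(model=model, train=train, test=test,
                          predictions=predictions, report=report)
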