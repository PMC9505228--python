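"""Ensemble inference: the predicted lesion count selects the output boxes.

A detector threshold sweep shows that no single preset confidence works
across lesion densities, so at inference the classifier's predicted count
``k`` replaces the confidence threshold: after ordinary non-max
suppression, the ``k`` highest-confidence candidates become the output.
The classifier's severity and count predictions ride along, and by default
the reported severity is recomputed from the predicted count through the
grading scheme so the two outputs can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations import AnnotatedImage, LesionBox, iou, normalize_image, resize_with_boxes
from .grading import GradingScheme, SeverityClass, severity_from_count
from .models import ClassifierNet, DetectorNet

__all__ = [
    "EnsemblePrediction",
    "nms",
    "confidence_filter",
    "count_guided_select",
    "predict",
]

DEFAULT_IOU_THRESHOLD = 0.45


@dataclass
class EnsemblePrediction:
    """Fused output: severity, count, and the count-guided box set.

    ``boxes`` are sorted by confidence descending and never number more
    than ``count``; ``shortfall`` flags the case where the detector offered
    fewer candidates than the predicted count.
    """

    severity: SeverityClass
    count: int
    boxes: list[LesionBox]
    shortfall: bool = False


def nms(candidates: Sequence[LesionBox], iou_threshold: float = DEFAULT_IOU_THRESHOLD) -> list[LesionBox]:
    """Greedy non-max suppression by descending confidence.

    No surviving pair overlaps above ``iou_threshold``; ties in confidence
    are broken by the earlier input index.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in [0, 1]")
    for b in candidates:
        if b.confidence is None:
            raise ValueError("nms requires candidate confidences")
    order = sorted(
        range(len(candidates)), key=lambda i: (-candidates[i].confidence, i)
    )
    kept: list[LesionBox] = []
    for i in order:
        if all(iou(candidates[i], k) <= iou_threshold for k in kept):
            kept.append(candidates[i])
    return kept


def confidence_filter(candidates: Sequence[LesionBox], conf: float) -> list[LesionBox]:
    """Boxes with confidence >= conf, input order preserved."""
    if not 0.0 <= conf <= 1.0:
        raise ValueError("confidence must be in [0, 1]")
    return [b for b in candidates if b.confidence is not None and b.confidence >= conf]


def count_guided_select(candidates: Sequence[LesionBox], k: int) -> list[LesionBox]:
    """The ``min(k, len(candidates))`` highest-confidence boxes.

    This is the fusion rule: the predicted lesion count, not a confidence
    threshold, decides how many detections are emitted.  Output is
    confidence-descending; ties keep the earlier input index.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    order = sorted(
        range(len(candidates)), key=lambda i: (-candidates[i].confidence, i)
    )
    return [candidates[i] for i in order[:k]]


def predict(
    image: AnnotatedImage | np.ndarray,
    classifier: ClassifierNet,
    detector: DetectorNet,
    scheme: GradingScheme | None = None,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    count_source: str = "classifier",
    consistent_severity: bool = True,
) -> EnsemblePrediction:
    """Run the full ensemble on one image.

    The count is the argmax of the count head (``count_source`` switches
    between the classification module and the detector's appended heads);
    the boxes are the count-guided top-k of the NMS-filtered detector
    candidates, mapped back to the original image scale.  With
    ``consistent_severity`` (default) the severity is recomputed from the
    predicted count through the grading scheme; otherwise the severity
    head's argmax is reported.
    """
    scheme = scheme or GradingScheme()
    if count_source not in ("classifier", "detector"):
        raise ValueError(f"unknown count_source {count_source!r}")
    if isinstance(image, np.ndarray):
        image = AnnotatedImage(
            image_id="query", width=image.shape[1], height=image.shape[0], pixels=image
        )

    def as_input(model) -> np.ndarray:
        img = image
        if img.width != model.spec.input_size or img.height != model.spec.input_size:
            img = resize_with_boxes(img, (model.spec.input_size, model.spec.input_size))
        x = normalize_image(img.pixels, model.norm_mean, model.norm_std)
        return np.ascontiguousarray(x.transpose(2, 0, 1))[None].astype(np.float64)

    det_outs, det_cls = detector.predict(as_input(detector))
    candidates = nms(det_outs[0].candidates, iou_threshold)

    if count_source == "detector":
        if det_cls is None:
            raise ValueError("detector has no classification heads")
        cls_out = det_cls
    else:
        cls_out = classifier.predict(as_input(classifier))
    k = int(cls_out.count_pred()[0])
    sev_code = int(cls_out.severity_pred()[0])

    boxes = count_guided_select(candidates, k)
    shortfall = len(boxes) < k

    # map boxes from detector input scale back to the original image
    sx = image.width / detector.spec.input_size
    sy = image.height / detector.spec.input_size
    if sx != 1.0 or sy != 1.0:
        boxes = [
            LesionBox(b.xmin * sx, b.ymin * sy, b.xmax * sx, b.ymax * sy, b.confidence)
            for b in boxes
        ]

    if consistent_severity:
        severity = severity_from_count(int(np.clip(k, 1, scheme.c_max)), scheme)
    else:
        severity = scheme.classes[sev_code]
    return EnsemblePrediction(severity=severity, count=k, boxes=boxes, shortfall=shortfall)
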