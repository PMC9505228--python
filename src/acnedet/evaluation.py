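"""Evaluation metrics: exact-match accuracies, count RMSE, the detector
confidence sweep, and box-level precision/recall at a fixed IoU.

``accuracy_number`` is exact count-category agreement — a deliberately
strict metric under which even strong models score low when counts are
large, which is precisely why the count-guided ensemble exists.  The
confidence sweep reproduces, at any scale, the experiment showing that the
detector's count error as a function of the preset confidence has an
interior optimum: too low a threshold overcounts, too high undercounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import AnnotatedImage, LesionBox, iou, normalize_image, resize_with_boxes
from .ensemble import confidence_filter, nms
from .grading import GradingScheme, severity_from_count
from .models import DetectorNet

__all__ = [
    "EvalReport",
    "accuracy",
    "rmse_count",
    "confidence_sweep",
    "box_pr",
    "plot_confidence_sweep",
]

DEFAULT_CONF_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass
class EvalReport:
    """Aggregate metrics over a dataset (optionally with sweep curves)."""

    accuracy_severity: float
    accuracy_number: float
    rmse_count: float
    n_images: int
    box_precision: float | None = None
    box_recall: float | None = None
    curves: dict[float, dict[str, float]] = field(default_factory=dict)

    def best_confidence(self, metric: str = "rmse_count") -> float:
        """Grid confidence minimizing RMSE (or maximizing an accuracy)."""
        if not self.curves:
            raise ValueError("no sweep curves in this report")
        sign = 1.0 if metric == "rmse_count" else -1.0
        return min(self.curves, key=lambda c: (sign * self.curves[c][metric], c))


def accuracy(preds: Sequence, truths: Sequence) -> float:
    """Fraction of exactly matching labels."""
    if len(preds) != len(truths) or len(preds) == 0:
        raise ValueError("prediction and truth lists must have equal nonzero length")
    return float(np.mean([int(p == t) for p, t in zip(preds, truths)]))


def rmse_count(pred_counts: Sequence[float], true_counts: Sequence[float]) -> float:
    """Root mean squared error between predicted and true counts."""
    p = np.asarray(pred_counts, dtype=float)
    t = np.asarray(true_counts, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("prediction and truth lists must have equal nonzero length")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def box_pr(
    pred_boxes: Sequence[LesionBox],
    true_boxes: Sequence[LesionBox],
    iou_threshold: float = 0.5,
) -> tuple[float, float]:
    """Greedy one-to-one precision/recall at an IoU threshold.

    Predictions are matched in descending confidence order (then input
    order); each ground-truth box can be matched once.
    """
    if not pred_boxes:
        return (1.0, 1.0) if not true_boxes else (1.0, 0.0)
    order = sorted(
        range(len(pred_boxes)),
        key=lambda i: (-(pred_boxes[i].confidence or 0.0), i),
    )
    matched_truth: set[int] = set()
    n_match = 0
    for i in order:
        best_j, best_v = -1, 0.0
        for j, t in enumerate(true_boxes):
            if j in matched_truth:
                continue
            v = iou(pred_boxes[i], t)
            if v >= iou_threshold and v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            matched_truth.add(best_j)
            n_match += 1
    precision = n_match / len(pred_boxes)
    recall = n_match / len(true_boxes) if true_boxes else 1.0
    return (precision, recall)


def _detector_inputs(
    dataset: Sequence[AnnotatedImage], detector: DetectorNet
) -> tuple[np.ndarray, list[AnnotatedImage]]:
    imgs = []
    for img in dataset:
        if img.width != detector.spec.input_size or img.height != detector.spec.input_size:
            img = resize_with_boxes(img, (detector.spec.input_size,) * 2)
        imgs.append(img)
    x = np.stack(
        [normalize_image(i.pixels, detector.norm_mean, detector.norm_std) for i in imgs]
    )
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)).astype(np.float64), imgs


def confidence_sweep(
    detector: DetectorNet,
    dataset: Sequence[AnnotatedImage],
    conf_grid: Sequence[float] = DEFAULT_CONF_GRID,
    iou_threshold: float = 0.45,
    scheme: GradingScheme | None = None,
    batch_size: int = 32,
) -> EvalReport:
    """Detector-only evaluation across preset confidence thresholds.

    At each confidence the per-image count is the number of boxes that
    survive NMS + confidence filtering, the severity is that count pushed
    through the grading scheme (clamped into its domain), and the three
    metrics are recorded.  Box counts are non-increasing in confidence.
    """
    if len(conf_grid) == 0:
        raise ValueError("empty confidence grid")
    scheme = scheme or GradingScheme()
    x, imgs = _detector_inputs(dataset, detector)
    true_counts = np.asarray([i.count for i in imgs])
    true_sev = np.asarray(
        [
            i.severity.code
            if i.severity is not None
            else severity_from_count(i.count, scheme).code
            for i in imgs
        ]
    )
    nms_boxes: list[list[LesionBox]] = []
    for start in range(0, len(imgs), batch_size):
        outs, _ = detector.predict(x[start : start + batch_size])
        nms_boxes.extend(nms(o.candidates, iou_threshold) for o in outs)

    curves: dict[float, dict[str, float]] = {}
    for conf in sorted(float(c) for c in conf_grid):
        counts = np.asarray([len(confidence_filter(b, conf)) for b in nms_boxes])
        sev = np.asarray(
            [
                severity_from_count(int(np.clip(c, 1, scheme.c_max)), scheme).code
                for c in counts
            ]
        )
        curves[conf] = {
            "accuracy_severity": float(np.mean(sev == true_sev)),
            "accuracy_number": float(np.mean(counts == true_counts)),
            "rmse_count": rmse_count(counts, true_counts),
            "mean_boxes": float(np.mean(counts)),
        }
    best = min(curves, key=lambda c: (curves[c]["rmse_count"], c))
    return EvalReport(
        accuracy_severity=curves[best]["accuracy_severity"],
        accuracy_number=curves[best]["accuracy_number"],
        rmse_count=curves[best]["rmse_count"],
        n_images=len(imgs),
        curves=curves,
    )


def plot_confidence_sweep(report: EvalReport, path: str) -> None:
    """Render the sweep curves (accuracies and count RMSE vs confidence).

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not report.curves:
        raise ValueError("no sweep curves in this report")
    grid = sorted(report.curves)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, [report.curves[c]["accuracy_severity"] for c in grid],
            "o-", label="accuracy_severity")
    ax.plot(grid, [report.curves[c]["accuracy_number"] for c in grid],
            "s-", label="accuracy_number")
    ax.set_xlabel("preset confidence")
    ax.set_ylabel("accuracy")
    ax2 = ax.twinx()
    ax2.plot(grid, [report.curves[c]["rmse_count"] for c in grid],
             "^--", color="tab:red", label="RMSE_count")
    ax2.set_ylabel("RMSE_count")
    lines, labels = ax.get_legend_handles_labels()
    l2, lab2 = ax2.get_legend_handles_labels()
    ax.legend(lines + l2, labels + lab2, loc="center right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
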