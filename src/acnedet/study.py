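"""Desk-scale reference study: the full pipeline on synthetic data.

This module wires the whole method together at a size a single CPU handles
in minutes, and is what the test suite and the reproduction script run:

1. generate a synthetic dataset (240 images, easy preset: counts 1..10),
2. stratified 80/20 split, then fixed-N resampling of the training side
   (N = median category size, giving ~200 training images over the 10
   count categories),
3. train the tiny classifier with the KL label-distribution loss and the
   tiny detector with appended heads (sequential strategy),
4. evaluate: held-out severity/count accuracy and count RMSE against the
   constant-mean-predictor baseline, ensemble box counts, the detector
   confidence sweep, and the high-density (hard preset) degradation.

Problem sizes and epoch counts here are the package's reference settings
for CPU experimentation; the same functions accept larger numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import AnnotatedImage
from .balancing import balance_by_count, split_train_test
from .ensemble import EnsemblePrediction, predict
from .evaluation import EvalReport, accuracy, confidence_sweep, rmse_count
from .losses import LossConfig
from .models import (
    BackboneSpec,
    ClassifierNet,
    DetectorNet,
    TrainingSchedule,
    _prepare,
    build_classifier,
    build_detector,
    train_classifier,
    train_detector,
)
from .synthetic import SyntheticSpec, easy_spec, generate_images, hard_spec

__all__ = [
    "StudyConfig",
    "ClassifierEval",
    "build_study_dataset",
    "train_study_classifier",
    "train_study_detector",
    "evaluate_classifier",
    "evaluate_ensemble",
    "run_easy_study",
    "run_hard_classifier",
]

# Reference settings: 240 generated images -> 80/20 split -> fixed-N
# balancing of the train side; 120 classifier epochs at batch 16; 40
# detector epochs per phase.  Chosen to finish in a few minutes on one CPU
# while the classifier converges on the easy preset.
N_IMAGES = 240
CLS_EPOCHS = 120
DET_EPOCHS = 40
CLS_LR = 0.01
CLS_BATCH = 16


@dataclass
class StudyConfig:
    n_images: int = N_IMAGES
    cls_epochs: int = CLS_EPOCHS
    det_epochs: int = DET_EPOCHS
    cls_lr: float = CLS_LR
    cls_batch: int = CLS_BATCH
    split_ratio: float = 0.8
    seed: int = 0


@dataclass
class ClassifierEval:
    accuracy_severity: float
    accuracy_number: float
    rmse_count: float
    rmse_baseline: float  # constant-mean predictor on the same test set
    n_images: int


def build_study_dataset(
    spec: SyntheticSpec, n_images: int, seed: int, split_ratio: float = 0.8
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Generate, split (stratified by severity), and balance the train side.

    Balancing uses N = median training category size, the package default
    when no N is given.
    """
    imgs = generate_images(n_images, spec, seed=seed)
    by_id = {i.image_id: i for i in imgs}
    sev = {i.image_id: i.severity.code for i in imgs}
    train_ids, test_ids = split_train_test(
        sorted(by_id), ratio=split_ratio, seed=seed + 1, severity_of=sev
    )
    index: dict[int, list[str]] = {}
    for i in train_ids:
        index.setdefault(by_id[i].count, []).append(i)
    n_bal = int(np.median([len(v) for v in index.values()]))
    balanced = balance_by_count(index, max(n_bal, 1), seed=seed + 2)
    return [by_id[i] for i in balanced], [by_id[i] for i in test_ids]


def train_study_classifier(
    train: Sequence[AnnotatedImage], cfg: StudyConfig
) -> tuple[ClassifierNet, list[dict]]:
    model = build_classifier(BackboneSpec("tiny_cnn"), seed=cfg.seed)
    sched = TrainingSchedule.classifier_default(
        epochs=cfg.cls_epochs, lr=cfg.cls_lr, batch_size=cfg.cls_batch, seed=cfg.seed
    )
    return train_classifier(model, train, LossConfig(kind="kl_divergence"), sched)


def train_study_detector(
    train: Sequence[AnnotatedImage], cfg: StudyConfig
) -> tuple[DetectorNet, list[dict]]:
    model = build_detector(BackboneSpec("tiny_detector"), with_cls_heads=True, seed=cfg.seed)
    sched = TrainingSchedule.detector_default(epochs=cfg.det_epochs, seed=cfg.seed)
    return train_detector(model, train, "sequential", LossConfig(), sched)


def evaluate_classifier(
    model: ClassifierNet,
    test: Sequence[AnnotatedImage],
    train: Sequence[AnnotatedImage] | None = None,
) -> ClassifierEval:
    """Held-out metrics; the RMSE baseline predicts the (rounded) mean
    training count for every image."""
    x, imgs = _prepare(test, model.spec.input_size, model.norm_mean, model.norm_std)
    out = model.predict(x)
    true_cnt = np.array([i.count for i in imgs])
    true_sev = np.array([i.severity.code for i in imgs])
    pred_cnt = out.count_pred()
    base = float(np.mean([i.count for i in (train or test)]))
    baseline = rmse_count(np.full(len(imgs), round(base)), true_cnt)
    return ClassifierEval(
        accuracy_severity=accuracy(list(out.severity_pred()), list(true_sev)),
        accuracy_number=accuracy(list(pred_cnt), list(true_cnt)),
        rmse_count=rmse_count(pred_cnt, true_cnt),
        rmse_baseline=baseline,
        n_images=len(imgs),
    )


def evaluate_ensemble(
    classifier: ClassifierNet,
    detector: DetectorNet,
    test: Sequence[AnnotatedImage],
) -> dict:
    preds: list[EnsemblePrediction] = [
        predict(img, classifier, detector) for img in test
    ]
    true_cnt = [i.count for i in test]
    true_sev = [i.severity.code for i in test]
    return {
        "accuracy_severity": accuracy([p.severity.code for p in preds], true_sev),
        "accuracy_number": accuracy([p.count for p in preds], true_cnt),
        "rmse_count": rmse_count([p.count for p in preds], true_cnt),
        "box_count_match_rate": float(
            np.mean([len(p.boxes) == p.count for p in preds])
        ),
        "shortfall_rate": float(np.mean([p.shortfall for p in preds])),
        "n_images": len(test),
    }


def run_easy_study(cfg: StudyConfig | None = None) -> dict:
    """Train and evaluate the full ensemble on the easy preset.

    Returns the trained models, the held-out classifier metrics, the
    ensemble metrics, and the detector confidence sweep over the training
    set (the overfit regime, where the interior-optimum effect shows).
    """
    cfg = cfg or StudyConfig()
    train, test = build_study_dataset(easy_spec(), cfg.n_images, cfg.seed, cfg.split_ratio)
    classifier, cls_log = train_study_classifier(train, cfg)
    detector, det_log = train_study_detector(train, cfg)
    cls_eval = evaluate_classifier(classifier, test, train)
    ens = evaluate_ensemble(classifier, detector, test)
    sweep = confidence_sweep(detector, train)
    return {
        "classifier": classifier,
        "detector": detector,
        "train": train,
        "test": test,
        "cls_log": cls_log,
        "det_log": det_log,
        "cls_eval": cls_eval,
        "ensemble": ens,
        "sweep": sweep,
    }


def run_hard_classifier(cfg: StudyConfig | None = None) -> ClassifierEval:
    """Classifier-only study on the high-density preset (counts > 50)."""
    cfg = cfg or StudyConfig()
    train, test = build_study_dataset(hard_spec(), cfg.n_images, cfg.seed, cfg.split_ratio)
    model, _ = train_study_classifier(train, cfg)
    return evaluate_classifier(model, test, train)
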