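"""Trainable classification and localization modules.

Two networks cover the pipeline:

* a **classifier** that encodes an image into a feature vector and applies
  two linear heads, one over severity classes and one over count
  categories.  The full-size family is a ResNet50-style bottleneck
  backbone (7x7 stem, max pool, four bottleneck stages, average pool); the
  ``tiny_cnn`` family is a four-conv stack behind the same contract, small
  enough to train on a CPU in seconds.

* a **detector** that produces three feature maps of decreasing spatial
  size plus a dense per-cell box/objectness map decoded into candidate
  boxes.  Optionally two fully connected classification heads are appended
  on the pooled multi-scale features so the detector can also predict
  severity and count.  ``yolo_like`` uses BN + SiLU conv blocks; the
  ``tiny_detector`` family is a plain conv stack behind the same contract.

Training is plain mini-batch gradient descent on the numpy layers of
``_nn``.  The classifier default schedule is momentum-SGD (batch 32,
lr 1e-3 halved every 30 epochs, momentum 0.9, weight decay 5e-4, 120
epochs); the detector default is Adam (batch 32, lr 3.2e-3 with a linear
decay factor from 1 to 0.12, beta1 0.843, weight decay 3.6e-4).  The
detector supports two strategies for its appended heads: ``sequential``
(train the detector, freeze it, then train the heads with the KL loss on
the frozen features) and ``joint`` (one optimization of
``alpha * loss_det + beta * loss_cls``, default 0.5/0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    Parameter,
    ReLU,
    SGD,
    Sequential,
    SiLU,
    sigmoid,
)
from .annotations import AnnotatedImage, LesionBox, normalize_image, resize_with_boxes
from .grading import (
    GradingScheme,
    count_label_distribution,
    severity_distribution_from_counts,
)
from .losses import (
    LossConfig,
    WeightScheme,
    combined_loss,
    compute_weights,
    cross_entropy_grad_logits,
    focal_grad_logits,
    kl_grad_logits,
)

__all__ = [
    "ClassifierOutput",
    "DetectorOutput",
    "BackboneSpec",
    "TrainingSchedule",
    "build_classifier",
    "build_detector",
    "train_classifier",
    "train_detector",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ClassifierOutput:
    """Raw head outputs in log-space; softmax is applied by the losses."""

    severity_logits: np.ndarray  # (N, S) or (S,)
    count_logits: np.ndarray  # (N, C_max) or (C_max,)

    def severity_pred(self) -> np.ndarray:
        return np.argmax(np.atleast_2d(self.severity_logits), axis=1)

    def count_pred(self) -> np.ndarray:
        """Predicted counts 1..C_max (argmax, ties toward the smaller count)."""
        return np.argmax(np.atleast_2d(self.count_logits), axis=1) + 1


@dataclass
class DetectorOutput:
    """One image's detector result: decoded candidates + raw multi-scale maps."""

    candidates: list[LesionBox]
    feature_maps: tuple[np.ndarray, np.ndarray, np.ndarray]


@dataclass
class BackboneSpec:
    """Architecture selection.

    ``family`` is one of ``resnet50_like``/``tiny_cnn`` (classification) or
    ``yolo_like``/``tiny_detector`` (localization).  ``input_size`` defaults
    to 224 for resnet50_like, 640 for yolo_like and 96 for the tiny desk-
    scale variants.  ``width`` scales channel counts (tiny variants stay
    under 1e6 parameters at width 1).
    """

    family: str = "tiny_cnn"
    input_size: int | None = None
    width: float = 1.0
    anchor: float = 10.0  # detector prior box side, pixels
    candidate_floor: float = 0.0  # drop decoded boxes below this confidence

    _DEFAULT_SIZES = {
        "resnet50_like": 224,
        "tiny_cnn": 96,
        "yolo_like": 640,
        "tiny_detector": 96,
    }

    def __post_init__(self) -> None:
        if self.family not in self._DEFAULT_SIZES:
            raise ValueError(f"unknown backbone family {self.family!r}")
        if self.input_size is None:
            self.input_size = self._DEFAULT_SIZES[self.family]
        if self.input_size % 32:
            raise ValueError("input_size must be a multiple of 32")


@dataclass
class TrainingSchedule:
    """Optimizer and learning-rate schedule for one training run."""

    epochs: int = 120
    batch_size: int = 32
    lr: float = 1e-3
    optimizer: str = "sgd"  # sgd | adam
    momentum: float = 0.9  # beta1 for adam
    weight_decay: float = 5e-4
    lr_decay: str = "step_half"  # step_half | linear | none
    step_size: int = 30
    end_factor: float = 0.12  # linear decay terminal factor
    seed: int = 0

    @classmethod
    def classifier_default(cls, **kw) -> "TrainingSchedule":
        return cls(**kw)

    @classmethod
    def detector_default(cls, **kw) -> "TrainingSchedule":
        defaults = dict(
            lr=0.0032,
            optimizer="adam",
            momentum=0.843,
            weight_decay=3.6e-4,
            lr_decay="linear",
        )
        defaults.update(kw)
        return cls(**defaults)

    def lr_at(self, epoch: int) -> float:
        if self.lr_decay == "step_half":
            return self.lr * 0.5 ** (epoch // self.step_size)
        if self.lr_decay == "linear":
            frac = epoch / max(self.epochs - 1, 1)
            return self.lr * (1.0 + (self.end_factor - 1.0) * frac)
        return self.lr

    def make_optimizer(self, params) -> SGD | Adam:
        if self.optimizer == "sgd":
            return SGD(params, self.lr, self.momentum, self.weight_decay)
        if self.optimizer == "adam":
            return Adam(params, self.lr, beta1=self.momentum, weight_decay=self.weight_decay)
        raise ValueError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# Classifier architectures
# ---------------------------------------------------------------------------

class _Bottleneck(Layer):
    """1x1 reduce -> 3x3 -> 1x1 expand with BN/ReLU and a residual shortcut."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, rng):
        self.branch = Sequential(
            Conv2d(in_ch, mid_ch, 1, 1, 0, rng, bias=False),
            BatchNorm2d(mid_ch),
            ReLU(),
            Conv2d(mid_ch, mid_ch, 3, stride, 1, rng, bias=False),
            BatchNorm2d(mid_ch),
            ReLU(),
            Conv2d(mid_ch, out_ch, 1, 1, 0, rng, bias=False),
            BatchNorm2d(out_ch),
        )
        self.short: Sequential | None = None
        if stride != 1 or in_ch != out_ch:
            self.short = Sequential(
                Conv2d(in_ch, out_ch, 1, stride, 0, rng, bias=False),
                BatchNorm2d(out_ch),
            )
        self._relu = ReLU()

    def parameters(self):
        ps = self.branch.parameters()
        if self.short is not None:
            ps += self.short.parameters()
        return ps

    def train(self, mode=True):
        self.training = mode
        self.branch.train(mode)
        if self.short is not None:
            self.short.train(mode)

    def forward(self, x):
        b = self.branch.forward(x)
        s = self.short.forward(x) if self.short is not None else x
        return self._relu.forward(b + s)

    def backward(self, dy):
        dy = self._relu.backward(dy)
        dx = self.branch.backward(dy)
        dx = dx + (self.short.backward(dy) if self.short is not None else dy)
        return dx


class ClassifierNet(Layer):
    """Backbone + GAP + two linear heads (severity, count)."""

    def __init__(self, spec: BackboneSpec, s_classes: int, c_max: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec, self.s_classes, self.c_max, self.seed = spec, s_classes, c_max, seed
        w = spec.width
        if spec.family == "tiny_cnn":
            chans = [max(4, int(c * w)) for c in (8, 16, 32, 32)]
            layers: list[Layer] = []
            prev = 3
            for c in chans:
                layers += [Conv2d(prev, c, 3, 2, 1, rng), ReLU()]
                prev = c
            self.backbone = Sequential(*layers)
            feat = prev
        elif spec.family == "resnet50_like":
            base = max(8, int(64 * w))
            stem = [
                Conv2d(3, base, 7, 2, 3, rng, bias=False),
                BatchNorm2d(base),
                ReLU(),
                MaxPool2d(2),
            ]
            blocks: list[Layer] = []
            in_ch = base
            stage_blocks = (3, 4, 6, 3)
            for i, nblocks in enumerate(stage_blocks):
                mid = base * 2**i
                out = mid * 4
                for b in range(nblocks):
                    stride = 2 if (b == 0 and i > 0) else 1
                    blocks.append(_Bottleneck(in_ch, mid, out, stride, rng))
                    in_ch = out
            self.backbone = Sequential(*(stem + blocks))
            feat = in_ch
        else:
            raise ValueError(f"{spec.family!r} is not a classifier family")
        self.gap = GlobalAvgPool()
        self.head_severity = Linear(feat, s_classes, rng)
        self.head_count = Linear(feat, c_max, rng)
        # normalization stats fitted at training time
        self.norm_mean = np.array([0.5, 0.5, 0.5])
        self.norm_std = np.array([0.25, 0.25, 0.25])

    def parameters(self):
        return (
            self.backbone.parameters()
            + self.head_severity.parameters()
            + self.head_count.parameters()
        )

    def train(self, mode=True):
        self.training = mode
        self.backbone.train(mode)

    def forward(self, x: np.ndarray) -> ClassifierOutput:
        f = self.gap.forward(self.backbone.forward(x))
        return ClassifierOutput(
            severity_logits=self.head_severity.forward(f),
            count_logits=self.head_count.forward(f),
        )

    def backward(self, d_sev: np.ndarray, d_cnt: np.ndarray) -> None:
        df = self.head_severity.backward(d_sev) + self.head_count.backward(d_cnt)
        self.backbone.backward(self.gap.backward(df))

    def predict(self, x: np.ndarray) -> ClassifierOutput:
        """Evaluation-mode forward pass."""
        self.train(False)
        return self.forward(x)


def build_classifier(
    spec: BackboneSpec | None = None,
    s_classes: int = 3,
    c_max: int = 65,
    seed: int = 0,
) -> ClassifierNet:
    """Build a severity/count classifier for the given backbone spec."""
    return ClassifierNet(spec or BackboneSpec("tiny_cnn"), s_classes, c_max, seed)


# ---------------------------------------------------------------------------
# Detector architectures
# ---------------------------------------------------------------------------

def _conv_block(in_ch, out_ch, rng, bn_silu: bool) -> Sequential:
    if bn_silu:
        return Sequential(
            Conv2d(in_ch, out_ch, 3, 2, 1, rng, bias=False),
            BatchNorm2d(out_ch),
            SiLU(),
        )
    return Sequential(Conv2d(in_ch, out_ch, 3, 2, 1, rng), ReLU())


class DetectorNet(Layer):
    """Multi-scale one-anchor detector with optional appended cls heads.

    The backbone emits feature maps at strides 4, 8 and 16; a 1x1 conv on
    the stride-8 map predicts per-cell ``(objectness, tx, ty, tw, th)``.
    Cell offsets go through a sigmoid, sizes are ``anchor * exp(t)``.  When
    classification heads are attached, the three maps are globally average
    pooled, concatenated and passed through two FC layers ending in the two
    heads.
    """

    STRIDE = 8

    def __init__(
        self,
        spec: BackboneSpec,
        with_cls_heads: bool,
        s_classes: int,
        c_max: int,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.spec, self.with_cls_heads = spec, with_cls_heads
        self.s_classes, self.c_max, self.seed = s_classes, c_max, seed
        w = spec.width
        bn = spec.family == "yolo_like"
        base = (16, 32, 64, 64) if bn else (8, 16, 32, 32)
        chans = [max(4, int(c * w)) for c in base]
        self.block1 = _conv_block(3, chans[0], rng, bn)  # stride 2
        self.block2 = _conv_block(chans[0], chans[1], rng, bn)  # stride 4 -> P1
        self.block3 = _conv_block(chans[1], chans[2], rng, bn)  # stride 8 -> P2
        self.block4 = _conv_block(chans[2], chans[3], rng, bn)  # stride 16 -> P3
        self.det_head = Conv2d(chans[2], 5, 1, 1, 0, rng)
        self._gap1, self._gap2, self._gap3 = (
            GlobalAvgPool(),
            GlobalAvgPool(),
            GlobalAvgPool(),
        )
        self._chans = chans
        if with_cls_heads:
            cat = chans[1] + chans[2] + chans[3]
            hidden = max(16, int(64 * w))
            self.fc1 = Linear(cat, hidden, rng)
            self._fc_relu = ReLU()
            self.head_severity = Linear(hidden, s_classes, rng)
            self.head_count = Linear(hidden, c_max, rng)
        self.norm_mean = np.array([0.5, 0.5, 0.5])
        self.norm_std = np.array([0.25, 0.25, 0.25])

    # -- parameter groups ---------------------------------------------------
    def backbone_parameters(self) -> list[Parameter]:
        return (
            self.block1.parameters()
            + self.block2.parameters()
            + self.block3.parameters()
            + self.block4.parameters()
            + self.det_head.parameters()
        )

    def head_parameters(self) -> list[Parameter]:
        if not self.with_cls_heads:
            return []
        return (
            self.fc1.parameters()
            + self.head_severity.parameters()
            + self.head_count.parameters()
        )

    def parameters(self):
        return self.backbone_parameters() + self.head_parameters()

    def train(self, mode=True):
        self.training = mode
        for b in (self.block1, self.block2, self.block3, self.block4):
            b.train(mode)

    # -- forward / backward -------------------------------------------------
    def forward_raw(self, x: np.ndarray) -> dict:
        s2 = self.block1.forward(x)
        p1 = self.block2.forward(s2)
        p2 = self.block3.forward(p1)
        p3 = self.block4.forward(p2)
        out = {"p1": p1, "p2": p2, "p3": p3, "det_map": self.det_head.forward(p2)}
        if self.with_cls_heads:
            cat = np.concatenate(
                [self._gap1.forward(p1), self._gap2.forward(p2), self._gap3.forward(p3)],
                axis=1,
            )
            h = self._fc_relu.forward(self.fc1.forward(cat))
            out["cls"] = ClassifierOutput(
                severity_logits=self.head_severity.forward(h),
                count_logits=self.head_count.forward(h),
            )
        return out

    def backward(
        self,
        d_det_map: np.ndarray | None,
        d_sev: np.ndarray | None = None,
        d_cnt: np.ndarray | None = None,
        through_backbone: bool = True,
    ) -> None:
        raw = self._last_raw
        d_p1 = np.zeros_like(raw["p1"])
        d_p2 = np.zeros_like(raw["p2"])
        d_p3 = np.zeros_like(raw["p3"])
        if d_sev is not None or d_cnt is not None:
            dh = np.zeros((raw["p1"].shape[0], self.head_severity.weight.data.shape[1]))
            if d_sev is not None:
                dh = dh + self.head_severity.backward(d_sev)
            if d_cnt is not None:
                dh = dh + self.head_count.backward(d_cnt)
            dcat = self.fc1.backward(self._fc_relu.backward(dh))
            c1, c2 = self._chans[1], self._chans[2]
            d_p1 += self._gap1.backward(dcat[:, :c1])
            d_p2 += self._gap2.backward(dcat[:, c1 : c1 + c2])
            d_p3 += self._gap3.backward(dcat[:, c1 + c2 :])
        if not through_backbone:
            return
        if d_det_map is not None:
            d_p2 += self.det_head.backward(d_det_map)
        d_p2 += self.block4.backward(d_p3)
        d_p1 += self.block3.backward(d_p2)
        self.block1.backward(self.block2.backward(d_p1))

    def forward(self, x: np.ndarray):
        """Forward pass caching intermediates for backward."""
        self._last_raw = self.forward_raw(x)
        return self._last_raw

    # -- decoding -----------------------------------------------------------
    def decode(self, det_map: np.ndarray) -> list[list[LesionBox]]:
        """Decode a raw (N, 5, Hg, Wg) map into per-image candidate boxes."""
        n, _, hg, wg = det_map.shape
        size = self.spec.input_size
        stride, anchor = size // hg, self.spec.anchor
        conf = sigmoid(det_map[:, 0])
        ox = sigmoid(det_map[:, 1])
        oy = sigmoid(det_map[:, 2])
        bw = anchor * np.exp(np.clip(det_map[:, 3], -4.0, 4.0))
        bh = anchor * np.exp(np.clip(det_map[:, 4], -4.0, 4.0))
        gx, gy = np.meshgrid(np.arange(wg), np.arange(hg))
        cx = (gx[None] + ox) * stride
        cy = (gy[None] + oy) * stride
        out: list[list[LesionBox]] = []
        for i in range(n):
            boxes = []
            keep = conf[i] >= self.spec.candidate_floor
            for y, x in zip(*np.nonzero(keep)):
                xmin = float(np.clip(cx[i, y, x] - bw[i, y, x] / 2, 0, size - 1))
                ymin = float(np.clip(cy[i, y, x] - bh[i, y, x] / 2, 0, size - 1))
                xmax = float(np.clip(cx[i, y, x] + bw[i, y, x] / 2, xmin + 1, size))
                ymax = float(np.clip(cy[i, y, x] + bh[i, y, x] / 2, ymin + 1, size))
                boxes.append(
                    LesionBox(xmin, ymin, xmax, ymax, confidence=float(conf[i, y, x]))
                )
            out.append(boxes)
        return out

    def predict(
        self, x: np.ndarray
    ) -> tuple[list[DetectorOutput], ClassifierOutput | None]:
        """Evaluation-mode forward: decoded candidates + feature maps."""
        self.train(False)
        raw = self.forward_raw(x)
        per_image = self.decode(raw["det_map"])
        outs = [
            DetectorOutput(
                candidates=boxes,
                feature_maps=(raw["p1"][i], raw["p2"][i], raw["p3"][i]),
            )
            for i, boxes in enumerate(per_image)
        ]
        return outs, raw.get("cls")


def build_detector(
    spec: BackboneSpec | None = None,
    with_cls_heads: bool = False,
    s_classes: int = 3,
    c_max: int = 65,
    seed: int = 0,
) -> DetectorNet:
    """Build a lesion detector, optionally with appended severity/count heads."""
    return DetectorNet(
        spec or BackboneSpec("tiny_detector"), with_cls_heads, s_classes, c_max, seed
    )


# ---------------------------------------------------------------------------
# Data preparation shared by the trainers
# ---------------------------------------------------------------------------

def fit_normalization(dataset: Sequence[AnnotatedImage]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of pixel intensities (on the 0..1 scale)."""
    px = np.stack([img.pixels for img in dataset]).astype(np.float64) / 255.0
    return px.mean(axis=(0, 1, 2)), np.maximum(px.std(axis=(0, 1, 2)), 1e-3)


def _prepare(
    dataset: Sequence[AnnotatedImage], input_size: int, mean, std
) -> tuple[np.ndarray, list[AnnotatedImage]]:
    """Resize to the model input size, normalize, and stack as NCHW."""
    imgs = []
    for img in dataset:
        if img.pixels is None:
            raise ValueError(f"image {img.image_id} has no pixel data")
        if img.width != input_size or img.height != input_size:
            img = resize_with_boxes(img, (input_size, input_size))
        imgs.append(img)
    x = np.stack([normalize_image(i.pixels, mean, std) for i in imgs])
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)).astype(np.float64), imgs


def _severity_codes(dataset: Sequence[AnnotatedImage], scheme: GradingScheme) -> np.ndarray:
    from .grading import severity_from_count

    codes = []
    for img in dataset:
        if img.severity is not None:
            codes.append(img.severity.code)
        else:
            codes.append(severity_from_count(img.count, scheme).code)
    return np.asarray(codes, dtype=int)


def _category_sizes(labels: np.ndarray, m: int) -> np.ndarray:
    return np.bincount(labels, minlength=m)


# ---------------------------------------------------------------------------
# Classifier training
# ---------------------------------------------------------------------------

def _head_loss_grad(logits, kind, *, true_idx=None, target=None, weights=None, focusing=2.0):
    if kind == "cross_entropy":
        return cross_entropy_grad_logits(logits, true_idx, weights)
    if kind == "focal":
        return focal_grad_logits(logits, true_idx, weights, focusing)
    if kind == "kl_divergence":
        return kl_grad_logits(logits, target)
    raise ValueError(kind)


def train_classifier(
    model: ClassifierNet,
    dataset: Sequence[AnnotatedImage],
    loss_config: LossConfig | None = None,
    schedule: TrainingSchedule | None = None,
    scheme: GradingScheme | None = None,
) -> tuple[ClassifierNet, list[dict]]:
    """Train the two-head classifier; returns the model and a per-epoch log.

    The loss kind applies to both heads: with cross-entropy/focal the
    targets are the severity code and the count category (count - 1), each
    with weights derived from the training-set category sizes under the
    configured scheme; with KL divergence the count target is the Gaussian
    label distribution and the severity target its mass aggregated over the
    grading ranges.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    cfg = loss_config or LossConfig()
    sched = schedule or TrainingSchedule.classifier_default()
    scheme = scheme or GradingScheme()

    model.norm_mean, model.norm_std = fit_normalization(dataset)
    x, imgs = _prepare(dataset, model.spec.input_size, model.norm_mean, model.norm_std)
    counts = np.asarray([img.count for img in imgs], dtype=int)
    sev = _severity_codes(imgs, scheme)
    cnt_idx = counts - 1

    if cfg.kind == "kl_divergence":
        cnt_targets = np.stack(
            [count_label_distribution(c, cfg.sigma, model.c_max).probs for c in counts]
        )
        sev_targets = np.stack(
            [
                severity_distribution_from_counts(
                    count_label_distribution(c, cfg.sigma, model.c_max), scheme
                )
                for c in counts
            ]
        )
        w_sev = w_cnt = None
    else:
        cnt_targets = sev_targets = None
        w_sev = compute_weights(_category_sizes(sev, model.s_classes), cfg.weight_scheme)
        w_cnt = compute_weights(_category_sizes(cnt_idx, model.c_max), cfg.weight_scheme)

    opt = sched.make_optimizer(model.parameters())
    rng = np.random.default_rng(sched.seed)
    log: list[dict] = []
    n = len(imgs)
    model.train(True)
    for epoch in range(sched.epochs):
        opt.lr = sched.lr_at(epoch)
        order = rng.permutation(n)
        ep_loss = 0.0
        pred_sev = np.empty(n, dtype=int)
        pred_cnt = np.empty(n, dtype=int)
        for start in range(0, n, sched.batch_size):
            idx = order[start : start + sched.batch_size]
            out = model.forward(x[idx])
            if cfg.kind == "kl_divergence":
                ls, gs = _head_loss_grad(out.severity_logits, cfg.kind, target=sev_targets[idx])
                lc, gc = _head_loss_grad(out.count_logits, cfg.kind, target=cnt_targets[idx])
            else:
                ls, gs = _head_loss_grad(
                    out.severity_logits, cfg.kind,
                    true_idx=sev[idx], weights=w_sev, focusing=cfg.focusing,
                )
                lc, gc = _head_loss_grad(
                    out.count_logits, cfg.kind,
                    true_idx=cnt_idx[idx], weights=w_cnt, focusing=cfg.focusing,
                )
            loss = ls + lc
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (severity {ls}, count {lc}); "
                    "reduce the learning rate or check the weight scheme"
                )
            opt.zero_grad()
            model.backward(gs, gc)
            opt.step()
            ep_loss += loss * len(idx)
            pred_sev[idx] = np.argmax(out.severity_logits, axis=1)
            pred_cnt[idx] = np.argmax(out.count_logits, axis=1) + 1
        log.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "loss": ep_loss / n,
                "accuracy_severity": float(np.mean(pred_sev == sev)),
                "accuracy_number": float(np.mean(pred_cnt == counts)),
                "rmse_count": float(np.sqrt(np.mean((pred_cnt - counts) ** 2.0))),
                "seed": sched.seed,
            }
        )
    model.train(False)
    return model, log


# ---------------------------------------------------------------------------
# Detector training
# ---------------------------------------------------------------------------

LAMBDA_BOX = 5.0
LAMBDA_NOOBJ = 0.5


def _detection_targets(
    imgs: Sequence[AnnotatedImage], grid: int, stride: int, anchor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell objectness and box-regression targets.

    Each ground-truth box is assigned to the grid cell containing its
    center; at most one box per cell (first wins).
    """
    n = len(imgs)
    tobj = np.zeros((n, grid, grid))
    tbox = np.zeros((n, 4, grid, grid))  # tx, ty, tw, th
    for i, img in enumerate(imgs):
        for b in img.boxes:
            cx, cy = b.center
            gx = min(int(cx // stride), grid - 1)
            gy = min(int(cy // stride), grid - 1)
            if tobj[i, gy, gx]:
                continue
            tobj[i, gy, gx] = 1.0
            tbox[i, 0, gy, gx] = cx / stride - gx
            tbox[i, 1, gy, gx] = cy / stride - gy
            tbox[i, 2, gy, gx] = np.log(max(b.width, 1.0) / anchor)
            tbox[i, 3, gy, gx] = np.log(max(b.height, 1.0) / anchor)
    return tobj, tbox


def _detection_loss_grad(
    det_map: np.ndarray, tobj: np.ndarray, tbox: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-balanced objectness BCE + box MSE on positive cells.

    Lesion cells are a tiny fraction of the grid, so the objectness loss
    averages the two classes separately (each contributes half); an
    unbalanced mean lets the background term drown the positive gradient.
    The background half is further scaled by LAMBDA_NOOBJ.
    """
    n, _, hg, wg = det_map.shape
    obj_logit = det_map[:, 0]
    p = sigmoid(obj_logit)
    pos = tobj > 0
    n_pos = max(int(pos.sum()), 1)
    n_neg = max(int((~pos).sum()), 1)
    w_cell = np.where(pos, 0.5 / n_pos, LAMBDA_NOOBJ * 0.5 / n_neg)
    eps = 1e-12
    bce = -np.sum(
        w_cell * (tobj * np.log(p + eps) + (1 - tobj) * np.log(1 - p + eps))
    )
    d_map = np.zeros_like(det_map)
    d_map[:, 0] = w_cell * (p - tobj)

    sxy = sigmoid(det_map[:, 1:3])
    dxy = sxy - tbox[:, 0:2]
    dwh = det_map[:, 3:5] - tbox[:, 2:4]
    posb = pos[:, None, :, :]
    box_mse = (np.sum(np.where(posb, dxy**2, 0.0)) + np.sum(np.where(posb, dwh**2, 0.0))) / n_pos
    d_map[:, 1:3] = np.where(posb, 2.0 * dxy * sxy * (1 - sxy), 0.0) * LAMBDA_BOX / n_pos
    d_map[:, 3:5] = np.where(posb, 2.0 * dwh, 0.0) * LAMBDA_BOX / n_pos
    return float(bce + LAMBDA_BOX * box_mse), d_map


def train_detector(
    model: DetectorNet,
    dataset: Sequence[AnnotatedImage],
    strategy: str = "sequential",
    loss_config: LossConfig | None = None,
    schedule: TrainingSchedule | None = None,
    scheme: GradingScheme | None = None,
) -> tuple[DetectorNet, list[dict]]:
    """Train the detector under the ``sequential`` or ``joint`` strategy.

    ``sequential`` optimizes the detection loss alone, then freezes the
    backbone (evaluation mode, parameters untouched) and trains the
    appended heads with the KL loss for ``schedule.epochs`` more epochs.
    ``joint`` optimizes ``alpha * det + beta * cls`` in one run and
    requires the heads to be present.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if strategy not in ("sequential", "joint"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "joint" and not model.with_cls_heads:
        raise ValueError("joint strategy requires with_cls_heads=True")
    cfg = loss_config or LossConfig()
    sched = schedule or TrainingSchedule.detector_default()
    scheme = scheme or GradingScheme()

    model.norm_mean, model.norm_std = fit_normalization(dataset)
    x, imgs = _prepare(dataset, model.spec.input_size, model.norm_mean, model.norm_std)
    grid = model.spec.input_size // DetectorNet.STRIDE
    tobj, tbox = _detection_targets(imgs, grid, DetectorNet.STRIDE, model.spec.anchor)
    counts = np.asarray([img.count for img in imgs], dtype=int)

    cls_targets = None
    if model.with_cls_heads:
        cnt_t = np.stack(
            [count_label_distribution(c, cfg.sigma, model.c_max).probs for c in counts]
        )
        sev_t = np.stack(
            [
                severity_distribution_from_counts(
                    count_label_distribution(c, cfg.sigma, model.c_max), scheme
                )
                for c in counts
            ]
        )
        cls_targets = (sev_t, cnt_t)

    rng = np.random.default_rng(sched.seed)
    n = len(imgs)
    log: list[dict] = []

    def run_phase(phase: str, params, epochs: int) -> None:
        opt = sched.make_optimizer(params)
        heads_only = phase == "heads"
        model.train(not heads_only)  # frozen backbone stays in eval mode
        for epoch in range(epochs):
            opt.lr = sched.lr_at(epoch)
            order = rng.permutation(n)
            ep_det = ep_cls = 0.0
            for start in range(0, n, sched.batch_size):
                idx = order[start : start + sched.batch_size]
                raw = model.forward(x[idx])
                det_loss, d_map = _detection_loss_grad(
                    raw["det_map"], tobj[idx], tbox[idx]
                )
                cls_loss, gs, gc = 0.0, None, None
                if model.with_cls_heads and phase != "det":
                    sev_t, cnt_t = cls_targets
                    ls, gs = kl_grad_logits(raw["cls"].severity_logits, sev_t[idx])
                    lc, gc = kl_grad_logits(raw["cls"].count_logits, cnt_t[idx])
                    cls_loss = ls + lc
                if phase == "det":
                    total = det_loss
                elif phase == "heads":
                    total = cls_loss
                else:  # joint
                    total = combined_loss(det_loss, cls_loss, cfg.joint_alpha, cfg.joint_beta)
                if not np.isfinite(total):
                    raise RuntimeError(f"non-finite loss in phase {phase} epoch {epoch}")
                opt.zero_grad()
                if phase == "det":
                    model.backward(d_map)
                elif phase == "heads":
                    model.backward(None, gs, gc, through_backbone=False)
                else:
                    model.backward(
                        cfg.joint_alpha * d_map,
                        cfg.joint_beta * gs,
                        cfg.joint_beta * gc,
                    )
                opt.step()
                ep_det += det_loss * len(idx)
                ep_cls += cls_loss * len(idx)
            log.append(
                {
                    "phase": phase,
                    "epoch": epoch,
                    "lr": opt.lr,
                    "det_loss": ep_det / n,
                    "cls_loss": ep_cls / n,
                    "total_loss": (
                        ep_det / n
                        if phase == "det"
                        else ep_cls / n
                        if phase == "heads"
                        else combined_loss(ep_det / n, ep_cls / n, cfg.joint_alpha, cfg.joint_beta)
                    ),
                    "seed": sched.seed,
                }
            )

    if strategy == "sequential":
        run_phase("det", model.backbone_parameters(), sched.epochs)
        if model.with_cls_heads:
            run_phase("heads", model.head_parameters(), sched.epochs)
    else:
        run_phase("joint", model.parameters(), sched.epochs)
    model.train(False)
    return model, log


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ClassifierNet | DetectorNet, path: str | Path) -> None:
    """Serialize parameters + architecture config + seed to an .npz file."""
    meta = {
        "kind": "classifier" if isinstance(model, ClassifierNet) else "detector",
        "family": model.spec.family,
        "input_size": model.spec.input_size,
        "width": model.spec.width,
        "anchor": model.spec.anchor,
        "candidate_floor": model.spec.candidate_floor,
        "s_classes": model.s_classes,
        "c_max": model.c_max,
        "seed": model.seed,
        "with_cls_heads": getattr(model, "with_cls_heads", None),
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["norm_mean"] = model.norm_mean
    arrays["norm_std"] = model.norm_std
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> ClassifierNet | DetectorNet:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    spec = BackboneSpec(
        family=meta["family"],
        input_size=meta["input_size"],
        width=meta["width"],
        anchor=meta["anchor"],
        candidate_floor=meta["candidate_floor"],
    )
    if meta["kind"] == "classifier":
        model = build_classifier(spec, meta["s_classes"], meta["c_max"], meta["seed"])
    else:
        model = build_detector(
            spec, meta["with_cls_heads"], meta["s_classes"], meta["c_max"], meta["seed"]
        )
    for i, p in enumerate(model.parameters()):
        p.data[...] = data[f"param_{i}"]
    model.norm_mean = data["norm_mean"]
    model.norm_std = data["norm_std"]
    model.train(False)
    return model
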