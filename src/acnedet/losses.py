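"""Classification losses and category re-weighting schemes.

Three losses are used to train the severity/count heads:

* weighted cross-entropy       L = -1/N sum_i w_{y_i} log x_{i,y_i}
* focal loss                   L = -1/N sum_i w_{y_i} (1 - x_{i,y_i})^a log x_{i,y_i}
* Kullback-Leibler divergence  L =  1/N sum_i sum_j y_ij (log y_ij - log x_ij)

with ``x`` predicted probabilities, ``y`` targets, ``w`` per-category
weights and ``a >= 0`` the focusing parameter (focal loss degenerates to
cross-entropy at ``a = 0``).  The KL loss is used with Gaussian count-label
distributions as targets (label distribution learning).

Category weights are derived from the per-category sample sizes ``n_j`` by
one of five schemes: all-ones, the raw sizes ``w_j = n_j``, min-max
normalization ``(w - w_min) / (w_max - w_min)``, standardization
``(w - mean) / std`` with the population standard deviation, or the
min-max result rescaled to sum to one.  The raw-size scheme deliberately
up-weights LARGE categories — that is how it is defined here and its
pathologies (standardized weights go negative and can collapse training)
are part of the behaviour under study.  An inverse-frequency scheme is
provided as a practical extra.

Joint detector training combines the detection loss and the appended
classification loss as ``alpha * det + beta * cls`` (default 0.5 / 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "WeightScheme",
    "LossConfig",
    "compute_weights",
    "weighted_cross_entropy",
    "focal_loss",
    "kl_divergence_loss",
    "combined_loss",
]

PROB_FLOOR = 1e-12


class WeightScheme(str, Enum):
    UNIFORM = "uniform"
    CATEGORY_SIZE = "category_size"
    MINMAX_NORMALIZED = "minmax_normalized"
    STANDARDIZED = "standardized"
    NORMALIZED_SUM_ONE = "normalized_sum_one"
    # not part of the study's five cases; the field-standard choice
    INVERSE_FREQUENCY = "inverse_frequency"


@dataclass
class LossConfig:
    """Loss selection for head training.

    ``kind`` picks the loss; ``weight_scheme`` how per-category weights are
    derived from training-set category sizes; ``focusing`` is the focal
    parameter (default 2); ``joint_alpha``/``joint_beta`` weight the
    detection and classification terms of the joint loss (default 0.5 each);
    ``sigma`` is the Gaussian label-distribution spread used with the KL
    loss.
    """

    kind: str = "kl_divergence"  # cross_entropy | focal | kl_divergence
    weight_scheme: WeightScheme = WeightScheme.UNIFORM
    focusing: float = 2.0
    joint_alpha: float = 0.5
    joint_beta: float = 0.5
    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("cross_entropy", "focal", "kl_divergence"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.focusing < 0:
            raise ValueError("focusing parameter must be >= 0")
        self.weight_scheme = WeightScheme(self.weight_scheme)

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        return cls(**d)


def compute_weights(
    category_sizes: Sequence[int], scheme: WeightScheme | str
) -> np.ndarray:
    """Per-category weight vector from sample sizes under a scheme."""
    scheme = WeightScheme(scheme)
    n = np.asarray(category_sizes, dtype=float)
    if np.any(n < 0):
        raise ValueError("category sizes must be non-negative")
    if scheme is WeightScheme.UNIFORM:
        return np.ones_like(n)
    if scheme is WeightScheme.CATEGORY_SIZE:
        return n.copy()
    if scheme is WeightScheme.INVERSE_FREQUENCY:
        total = n.sum()
        if total == 0:
            raise ValueError("all category sizes are zero")
        safe = np.where(n > 0, n, np.nan)
        w = total / (np.count_nonzero(n) * safe)
        return np.nan_to_num(w, nan=0.0)
    # the remaining schemes rescale the raw sizes
    if np.ptp(n) == 0:
        raise ValueError(
            f"{scheme.value}: degenerate scale, all category sizes equal"
        )
    if scheme is WeightScheme.STANDARDIZED:
        return (n - n.mean()) / n.std()  # population std
    w = (n - n.min()) / (n.max() - n.min())
    if scheme is WeightScheme.MINMAX_NORMALIZED:
        return w
    if scheme is WeightScheme.NORMALIZED_SUM_ONE:
        return w / w.sum()
    raise AssertionError(f"unhandled scheme {scheme}")


def _as_batch(pred_probs: np.ndarray) -> np.ndarray:
    p = np.asarray(pred_probs, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    return p


def _weights_for(weights, m: int) -> np.ndarray:
    if weights is None:
        return np.ones(m)
    w = np.asarray(weights, dtype=float)
    if np.isscalar(weights) or w.ndim == 0:
        return np.full(m, float(w))
    if w.shape != (m,):
        raise ValueError(f"weight vector length {w.shape} != number of classes {m}")
    return w


def weighted_cross_entropy(
    pred_probs: np.ndarray, true_index, weights=None
) -> float:
    """Mean weighted cross-entropy over a batch of probability vectors."""
    p = _as_batch(pred_probs)
    y = np.atleast_1d(np.asarray(true_index, dtype=int))
    w = _weights_for(weights, p.shape[1])
    pt = np.clip(p[np.arange(len(y)), y], PROB_FLOOR, None)
    return float(np.mean(-w[y] * np.log(pt)))


def focal_loss(
    pred_probs: np.ndarray, true_index, weights=None, focusing: float = 2.0
) -> float:
    """Mean focal loss; the modulating factor ``(1 - x)^focusing`` damps
    the contribution of well-classified samples."""
    if focusing < 0:
        raise ValueError("focusing parameter must be >= 0")
    p = _as_batch(pred_probs)
    y = np.atleast_1d(np.asarray(true_index, dtype=int))
    w = _weights_for(weights, p.shape[1])
    pt = np.clip(p[np.arange(len(y)), y], PROB_FLOOR, None)
    return float(np.mean(-w[y] * (1.0 - pt) ** focusing * np.log(pt)))


def kl_divergence_loss(
    pred_log_probs: np.ndarray, target_dist: np.ndarray
) -> float:
    """Mean KL divergence ``sum_j y_j (log y_j - log x_j)`` over a batch.

    Predictions are passed in log space (log-softmax of logits); targets are
    probability vectors summing to 1 within 1e-6.  ``0 * log 0`` is 0.
    """
    logx = _as_batch(pred_log_probs)
    y = _as_batch(target_dist)
    if logx.shape != y.shape:
        raise ValueError("prediction and target shapes differ")
    sums = y.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("target distribution not normalized within 1e-6")
    if np.any(y < 0):
        raise ValueError("target distribution has negative entries")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * (np.log(y) - logx), 0.0)
    return float(np.mean(term.sum(axis=1)))


def combined_loss(
    det_loss: float, cls_loss: float, joint_alpha: float = 0.5, joint_beta: float = 0.5
) -> float:
    """Joint training objective ``alpha * det_loss + beta * cls_loss``."""
    if not (np.isfinite(det_loss) and np.isfinite(cls_loss)):
        raise ValueError("losses must be finite")
    return joint_alpha * det_loss + joint_beta * cls_loss


# ---------------------------------------------------------------------------
# Analytic gradients w.r.t. logits (used by the training loops)
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def cross_entropy_grad_logits(
    logits: np.ndarray, true_index: np.ndarray, weights=None
) -> tuple[float, np.ndarray]:
    """Weighted CE loss and its gradient w.r.t. logits (mean over batch)."""
    z = _as_batch(logits)
    y = np.atleast_1d(np.asarray(true_index, dtype=int))
    w = _weights_for(weights, z.shape[1])
    p = softmax(z)
    n = len(y)
    loss = weighted_cross_entropy(p, y, w)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    grad = w[y][:, None] * (p - onehot) / n
    return loss, grad


def focal_grad_logits(
    logits: np.ndarray, true_index: np.ndarray, weights=None, focusing: float = 2.0
) -> tuple[float, np.ndarray]:
    """Focal loss and gradient w.r.t. logits.

    The loss depends on the softmax only through the true-class probability
    p_t, so d loss / d z_j = (d loss / d p_t) * p_t (delta_tj - p_j).
    """
    z = _as_batch(logits)
    y = np.atleast_1d(np.asarray(true_index, dtype=int))
    w = _weights_for(weights, z.shape[1])
    p = softmax(z)
    n = len(y)
    idx = np.arange(n)
    pt = np.clip(p[idx, y], PROB_FLOOR, 1.0 - PROB_FLOOR)
    one_minus = 1.0 - pt
    loss = float(np.mean(-w[y] * one_minus**focusing * np.log(pt)))
    if focusing == 0.0:
        dpt = -w[y] / pt
    else:
        # d/dpt of  -w (1-pt)^a log pt
        dpt = -w[y] * (
            -focusing * one_minus ** (focusing - 1.0) * np.log(pt)
            + one_minus**focusing / pt
        )
    grad = dpt[:, None] / n * pt[:, None] * (-p)
    grad[idx, y] += dpt / n * pt * 1.0
    return loss, grad


def kl_grad_logits(
    logits: np.ndarray, target_dist: np.ndarray
) -> tuple[float, np.ndarray]:
    """KL loss and gradient w.r.t. logits: (softmax(z) - y) / N."""
    z = _as_batch(logits)
    y = _as_batch(target_dist)
    logp = log_softmax(z)
    loss = kl_divergence_loss(logp, y)
    grad = (softmax(z) - y) / z.shape[0]
    return loss, grad
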