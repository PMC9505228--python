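"""Severity grading from lesion counts and Gaussian count-label distributions.

Clinical grading of acne by lesion count (a simplified Hayashi-style scale)
maps the number of lesions in a half-face image to an ordinal severity class.
The default three-class scheme is: mild for 1-5 lesions, moderate for 6-20,
severe for more than 20, with counts supported on 1..65.

For label-distribution learning the integer count label ``mu`` is softened
into a discrete Gaussian over the count categories: the probability of
category ``x`` is proportional to ``exp(-(x - mu)^2 / (2 sigma^2))``,
evaluated at the integer bins and renormalized so the truncation at the
support boundaries is absorbed.  The default spread is ``sigma = 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SeverityClass",
    "GradingScheme",
    "LabelDistribution",
    "severity_from_count",
    "count_label_distribution",
    "severity_distribution_from_counts",
]

DEFAULT_C_MAX = 65
DEFAULT_SIGMA = 3.0


@dataclass(frozen=True)
class SeverityClass:
    """Ordinal severity level: contiguous code ``0..S-1`` plus a name."""

    code: int
    name: str

    def __int__(self) -> int:
        return self.code


@dataclass(frozen=True)
class GradingScheme:
    """Count-to-severity mapping defined by inclusive upper bounds per class.

    ``thresholds[s]`` is the largest count still graded as class ``s``; the
    last threshold equals ``c_max``.  The default is the three-level scheme
    (mild<=5, moderate<=20, severe<=65).  A four-level Hayashi-style variant
    is available as :meth:`hayashi4`.
    """

    thresholds: tuple[int, ...] = (5, 20, DEFAULT_C_MAX)
    names: tuple[str, ...] = ("mild", "moderate", "severe")

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.names):
            raise ValueError("thresholds and names must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.thresholds[0] < 1:
            raise ValueError("first threshold must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds)

    @property
    def c_max(self) -> int:
        return self.thresholds[-1]

    @property
    def classes(self) -> tuple[SeverityClass, ...]:
        return tuple(SeverityClass(i, n) for i, n in enumerate(self.names))

    @classmethod
    def hayashi4(cls, c_max: int = DEFAULT_C_MAX) -> "GradingScheme":
        """Four-level variant keeping the >50 'very severe' class."""
        return cls(
            thresholds=(5, 20, 50, max(c_max, 51)),
            names=("mild", "moderate", "severe", "very severe"),
        )

    def to_dict(self) -> dict:
        return {"thresholds": list(self.thresholds), "names": list(self.names)}

    @classmethod
    def from_dict(cls, d: dict) -> "GradingScheme":
        return cls(tuple(d["thresholds"]), tuple(d["names"]))


@dataclass
class LabelDistribution:
    """Discrete probability vector over count categories ``1..c_max``.

    ``probs[i]`` is the probability of count ``i + 1``; ``mu`` is the true
    count the distribution was built around and ``sigma`` its spread.
    """

    probs: np.ndarray
    mu: float
    sigma: float
    c_max: int = field(default=DEFAULT_C_MAX)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.c_max,):
            raise ValueError(
                f"probs must have length c_max={self.c_max}, got {self.probs.shape}"
            )
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    @property
    def counts(self) -> np.ndarray:
        """The integer support 1..c_max."""
        return np.arange(1, self.c_max + 1)

    def argmax_count(self) -> int:
        """Most probable count (ties broken toward the smaller count)."""
        return int(np.argmax(self.probs)) + 1


def severity_from_count(count: int, scheme: GradingScheme | None = None) -> SeverityClass:
    """Grade a lesion count.

    Piecewise-constant and non-decreasing in ``count``; raises for counts
    outside ``[1, scheme.c_max]``.
    """
    scheme = scheme or GradingScheme()
    count = int(count)
    if count < 1 or count > scheme.c_max:
        raise ValueError(f"count {count} outside grading domain [1, {scheme.c_max}]")
    for cls_, upper in zip(scheme.classes, scheme.thresholds):
        if count <= upper:
            return cls_
    raise AssertionError("unreachable: last threshold equals c_max")


def count_label_distribution(
    mu: float, sigma: float = DEFAULT_SIGMA, c_max: int = DEFAULT_C_MAX
) -> LabelDistribution:
    """Discrete Gaussian label distribution centred on the true count ``mu``.

    The Gaussian density is evaluated at the integer bins ``1..c_max`` and
    renormalized, so boundary truncation is absorbed and the result is a
    valid distribution peaking at ``round(mu)``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 1 <= mu <= c_max:
        raise ValueError(f"mu={mu} outside [1, {c_max}]")
    x = np.arange(1, c_max + 1, dtype=float)
    # log-space for numerical stability at tiny sigma (near-one-hot limit)
    logp = -((x - mu) ** 2) / (2.0 * sigma**2)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return LabelDistribution(probs=p, mu=float(mu), sigma=float(sigma), c_max=c_max)


def severity_distribution_from_counts(
    dist: LabelDistribution, scheme: GradingScheme | None = None
) -> np.ndarray:
    """Aggregate a count distribution into a severity-class distribution.

    Each severity class receives the total probability mass of the count
    bins that grade to it; the output sums to 1 exactly as the input does.
    """
    scheme = scheme or GradingScheme()
    if scheme.c_max != dist.c_max:
        raise ValueError(
            f"scheme c_max {scheme.c_max} does not match distribution c_max {dist.c_max}"
        )
    out = np.zeros(scheme.n_classes)
    lower = 1
    for s, upper in enumerate(scheme.thresholds):
        out[s] = dist.probs[lower - 1 : upper].sum()
        lower = upper + 1
    return out


def severity_codes_for_counts(
    counts: Sequence[int], scheme: GradingScheme | None = None
) -> np.ndarray:
    """Vectorized helper: severity code for each count in a sequence."""
    scheme = scheme or GradingScheme()
    counts = np.asarray(counts, dtype=int)
    codes = np.searchsorted(np.asarray(scheme.thresholds), counts, side="left")
    if np.any(counts < 1) or np.any(counts > scheme.c_max):
        raise ValueError("count outside grading domain")
    return codes
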