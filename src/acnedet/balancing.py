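"""Count-category rebalancing and stratified train/test splitting.

Real lesion-count datasets are severely long-tailed: a handful of low-count
categories hold most of the images while high-count categories may hold a
single image (ratios above 160x).  Training a per-count classifier on such
data is dominated by the head of the distribution, so the sample
distribution is smoothed by fixed-N resampling: every non-empty count
category is brought to exactly N images, by sampling without replacement
when a category is larger than N and by duplication (cycling a shuffled
list) when it is smaller.

Splitting happens BEFORE balancing and balancing is applied to the training
side only, so a duplicated image can never leak into the test set.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

__all__ = ["CategoryIndex", "balance_by_count", "split_train_test"]

# count value -> list of image ids holding that count
CategoryIndex = Mapping[int, Sequence[str]]


def balance_by_count(index: CategoryIndex, n: int, seed: int) -> list[str]:
    """Resample every non-empty count category to exactly ``n`` image ids.

    Categories larger than ``n`` are sampled without replacement; smaller
    ones are duplicated by cycling a shuffled copy, so every original image
    appears at least ``floor(n / size)`` times.  Deterministic given
    ``seed``.  Output is ordered by ascending count category.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    nonempty = {c: ids for c, ids in index.items() if len(ids) > 0}
    if not nonempty:
        raise ValueError("empty category index")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for count in sorted(nonempty):
        ids = list(nonempty[count])
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        if len(shuffled) >= n:
            out.extend(shuffled[:n])
        else:
            out.extend(shuffled[i % len(shuffled)] for i in range(n))
    return out


def split_train_test(
    ids: Sequence[str],
    ratio: float = 0.8,
    seed: int = 0,
    severity_of: Mapping[str, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Disjoint train/test partition with ``|train| = round(ratio * |ids|)``.

    When ``severity_of`` maps each id to its severity code the split is
    stratified: every class contributes train images in proportion to its
    size (largest-remainder rounding keeps the overall ratio exact).  A
    class with fewer than 2 images is kept whole in train, with a warning.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ids to split")
    rng = np.random.default_rng(seed)
    n_train_total = int(round(ratio * len(ids)))

    if severity_of is None:
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        return shuffled[:n_train_total], shuffled[n_train_total:]

    strata: dict[int, list[str]] = {}
    for i in ids:
        strata.setdefault(severity_of[i], []).append(i)

    # proportional allocation, largest remainder
    keys = sorted(strata)
    exact = {k: ratio * len(strata[k]) for k in keys}
    alloc = {k: int(np.floor(exact[k])) for k in keys}
    shortfall = n_train_total - sum(alloc.values())
    for k in sorted(keys, key=lambda k: exact[k] - alloc[k], reverse=True):
        if shortfall <= 0:
            break
        alloc[k] += 1
        shortfall -= 1

    train: list[str] = []
    test: list[str] = []
    for k in keys:
        members = strata[k]
        if len(members) < 2:
            warnings.warn(
                f"severity class {k} has <2 images; kept whole in train",
                stacklevel=2,
            )
            train.extend(members)
            continue
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        train.extend(shuffled[: alloc[k]])
        test.extend(shuffled[alloc[k] :])
    return train, test
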