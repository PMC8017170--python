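"""Binary-relevance task construction, class balancing and partitioning.

The multi-label corpus is decomposed into one binary task per abnormality
(a record is positive for every label it carries).  Each task is balanced
by random under-sampling of the majority class to a 2:1 majority:minority
ratio, then partitioned 64/16/20 into train/validation/test (largest-
remainder rounding, stratified by default) or into stratified k folds.

Splitting is record-level: all frames derived from one record share its
partition, so no signal leaks across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .records import DEFAULT_CLASSES, ECGRecord


class BalanceError(ValueError):
    """Raised when a binary task cannot be balanced (a class is empty)."""


@dataclass
class BinaryTask:
    """One abnormality's binary-relevance dataset."""

    target_class: str
    record_ids: list[str]
    labels: np.ndarray  # 0/1, aligned with record_ids
    ratio: float        # achieved majority:minority ratio
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.record_ids) != len(self.labels):
            raise ValueError("record_ids and labels must align 1:1")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def __len__(self) -> int:
        return len(self.record_ids)


@dataclass(frozen=True)
class SplitSpec:
    """Partition fractions, fold count and stratification policy."""

    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    k: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError(f"fractions must be positive, got {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")


def binarize(records: list[ECGRecord], target_class: str,
             vocabulary: tuple[str, ...] = DEFAULT_CLASSES) -> BinaryTask:
    """Build the (unbalanced) binary task for one abnormality.

    A record is labelled 1 iff ``target_class`` is in its label set, so a
    multi-label record contributes a positive example to each of its
    classes.
    """
    if target_class not in vocabulary:
        raise ValueError(
            f"target class {target_class!r} not in vocabulary {list(vocabulary)}"
        )
    labels = np.array([int(target_class in r.labels) for r in records], dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ratio = (max(n_pos, n_neg) / min(n_pos, n_neg)) if min(n_pos, n_neg) else float("inf")
    return BinaryTask(
        target_class=target_class,
        record_ids=[r.record_id for r in records],
        labels=labels,
        ratio=ratio,
    )


def undersample(task: BinaryTask, ratio: float = 2.0, seed: int = 0) -> BinaryTask:
    """Random under-sampling of the majority class to ``ratio`` : 1.

    Every minority record is kept; ``floor(ratio * n_minority)`` majority
    records are drawn uniformly without replacement (all of them if fewer
    are available).  The output order is a deterministic shuffle of the
    selection under ``seed``.
    """
    pos_idx = np.flatnonzero(task.labels == 1)
    neg_idx = np.flatnonzero(task.labels == 0)
    if len(pos_idx) == 0:
        raise BalanceError(f"no positive records for class {task.target_class!r}")
    if len(neg_idx) == 0:
        raise BalanceError(f"no negative records for class {task.target_class!r}")
    minority, majority = (pos_idx, neg_idx) if len(pos_idx) <= len(neg_idx) else (neg_idx, pos_idx)
    n_keep = min(len(majority), int(np.floor(ratio * len(minority))))
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=n_keep, replace=False)
    selected = np.concatenate([minority, kept_majority])
    rng.shuffle(selected)
    labels = task.labels[selected]
    n_pos, n_neg = int(labels.sum()), int(len(labels) - labels.sum())
    return BinaryTask(
        target_class=task.target_class,
        record_ids=[task.record_ids[i] for i in selected],
        labels=labels,
        ratio=max(n_pos, n_neg) / min(n_pos, n_neg),
        seed=seed,
    )


def _largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer partition sizes by largest-remainder rounding (total preserved)."""
    ideal = np.asarray(fractions, dtype=float) * n
    sizes = np.floor(ideal).astype(int)
    remainders = ideal - sizes
    shortfall = n - sizes.sum()
    # Hand the leftover records to the partitions with the largest remainders.
    for j in np.argsort(-remainders, kind="stable")[:shortfall]:
        sizes[j] += 1
    return sizes.tolist()


def _partition_indices(indices: np.ndarray, fractions: tuple[float, ...],
                       rng: np.random.Generator) -> list[np.ndarray]:
    shuffled = rng.permutation(indices)
    sizes = _largest_remainder_sizes(len(indices), fractions)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(shuffled[start:start + s]))
        start += s
    return out


def split(task: BinaryTask, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train / validation / test index sets (disjoint cover of the task).

    Sizes follow largest-remainder rounding of the fractions.  When
    stratified, rounding is applied within each class so every partition's
    class proportions match the whole task within one record per class.
    """
    n = len(task)
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        parts: list[list[np.ndarray]] = [[], [], []]
        for value in (0, 1):
            cls_idx = np.flatnonzero(task.labels == value)
            for bucket, chunk in zip(parts, _partition_indices(cls_idx, spec.fractions, rng)):
                bucket.append(chunk)
        result = tuple(np.sort(np.concatenate(b)) for b in parts)
    else:
        result = tuple(_partition_indices(np.arange(n), spec.fractions, rng))
    if any(len(p) == 0 for p in result):
        raise ValueError(
            f"a partition would be empty for n={n} with fractions {spec.fractions}"
        )
    return result


def kfold(task: BinaryTask, spec: SplitSpec = SplitSpec()) -> list[tuple[np.ndarray, np.ndarray]]:
    """k (train, validation) index-set pairs for cross-validation.

    Folds are disjoint, cover all indices, and differ in size by at most
    one; stratified folds additionally preserve the class ratio.
    """
    n = len(task)
    if spec.k > n:
        raise ValueError(f"k={spec.k} exceeds record count {n}")
    if spec.stratified:
        n_minority = min(int(task.labels.sum()), int(n - task.labels.sum()))
        if spec.k > n_minority:
            raise ValueError(
                f"stratified k={spec.k} exceeds minority count {n_minority}"
            )
        splitter = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    else:
        splitter = KFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    return [
        (np.sort(tr), np.sort(va))
        for tr, va in splitter.split(np.zeros(n), task.labels)
    ]
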