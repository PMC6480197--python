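"""Evaluation protocol: confusion metrics, stratified k-fold CV, balancing.

Abnormal is the positive class by default -- it is the detection target
that triggers caregiver alarms.  Metrics follow the standard confusion
identities: accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall =
TP/(TP+FN), F = harmonic mean of precision and recall.  Ratios with a
zero denominator are reported as undefined (None), never coerced to 0.

Cross-validation is stratified and seeded; mining and classification are
re-run from scratch inside every fold, and class balancing (seeded
random oversampling of the minority class to parity) is applied to the
training portion of each fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .car_miner import ItemizationScheme, itemize, mine_cars
from .cdea import ABNORMAL, BehaviorInstance
from .lac import LazyClassifier


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricEntry:
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f_measure: Optional[float]
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f_measure": self.f_measure,
                "tp": self.counts.tp, "tn": self.counts.tn,
                "fp": self.counts.fp, "fn": self.counts.fn}


def compute_metrics(counts: ConfusionCounts) -> MetricEntry:
    """Accuracy, precision, recall and F from raw confusion counts."""
    if counts.total == 0:
        raise EvaluationError("no evaluated instances")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = (counts.tp / (counts.tp + counts.fp)
                 if counts.tp + counts.fp else None)
    recall = (counts.tp / (counts.tp + counts.fn)
              if counts.tp + counts.fn else None)
    if precision is not None and recall is not None and precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f = 0.0
    else:
        f = None
    return MetricEntry(accuracy, precision, recall, f, counts)


def confusion_from_labels(true: Sequence[str], predicted: Sequence[str],
                          positive_class: str = ABNORMAL) -> ConfusionCounts:
    tp = tn = fp = fn = 0
    for t, p in zip(true, predicted):
        if p == positive_class:
            if t == positive_class:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive_class:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def balance_classes(dataset: Sequence[tuple[frozenset, str]],
                    seed: int = 0,
                    method: str = "replicate") -> list[tuple[frozenset, str]]:
    """Seeded random oversampling of minority classes to parity.

    ``method="replicate"`` (default) duplicates every minority instance
    the same whole number of times and fills the remainder with a seeded
    draw without replacement, so per-instance duplication counts differ
    by at most one; ``method="sample"`` draws the whole deficit with
    replacement.  Replication is the default because uneven duplication
    multiplicities distort the confidence and information gain of the
    rules mined downstream.  An already balanced dataset is returned
    unchanged.  No synthetic instances are invented: only existing ones
    are repeated, so every attribute combination in the output occurred
    in the input.
    """
    if method not in ("replicate", "sample"):
        raise EvaluationError(f"unknown balancing method {method!r}")
    labels = [lab for _, lab in dataset]
    classes = sorted(set(labels))
    if len(classes) < 2:
        return list(dataset)
    rng = np.random.default_rng(seed)
    by_class = {c: [d for d in dataset if d[1] == c] for c in classes}
    target = max(len(v) for v in by_class.values())
    out = list(dataset)
    for c in classes:
        pool = by_class[c]
        deficit = target - len(pool)
        if deficit <= 0:
            continue
        if method == "sample":
            picks = rng.integers(0, len(pool), size=deficit)
        else:
            whole, rem = divmod(deficit, len(pool))
            picks = list(range(len(pool))) * whole
            picks += list(rng.choice(len(pool), size=rem, replace=False))
        out.extend(pool[i] for i in picks)
    return out


@dataclass
class MetricReport:
    per_fold: list[MetricEntry]
    pooled: MetricEntry
    weighted: MetricEntry
    #: out-of-fold predicted label per input instance
    predictions: Optional[list[str]] = None

    def to_dict(self) -> dict:
        return {"per_fold": [m.to_dict() for m in self.per_fold],
                "pooled": self.pooled.to_dict(),
                "weighted": self.weighted.to_dict()}


def _weighted_mean(entries: list[MetricEntry], attr: str) -> Optional[float]:
    pairs = [(getattr(m, attr), m.counts.total) for m in entries
             if getattr(m, attr) is not None]
    if not pairs:
        return None
    w = sum(n for _, n in pairs)
    return sum(v * n for v, n in pairs) / w


def aggregate_weighted(entries: list[MetricEntry]) -> MetricEntry:
    """Instance-count-weighted mean of per-fold (or per-subject) metrics."""
    pooled_counts = sum((m.counts for m in entries), ConfusionCounts())
    return MetricEntry(
        accuracy=_weighted_mean(entries, "accuracy"),
        precision=_weighted_mean(entries, "precision"),
        recall=_weighted_mean(entries, "recall"),
        f_measure=_weighted_mean(entries, "f_measure"),
        counts=pooled_counts,
    )


def cross_validate(instances: Sequence[BehaviorInstance],
                   k: int = 10,
                   seed: int = 0,
                   scheme: ItemizationScheme | None = None,
                   min_support: float = 0.01,
                   min_confidence: float = 0.5,
                   max_antecedent_len: int = 7,
                   balance: bool = True,
                   positive_class: str = ABNORMAL,
                   fallback_class: str = ABNORMAL,
                   ) -> MetricReport:
    """Stratified k-fold cross-validation of the mine-then-classify pipeline.

    Each fold mines a fresh CAR base from its (optionally balanced)
    training portion and lazily classifies the untouched test portion.
    """
    scheme = scheme or ItemizationScheme()
    labels = [inst.class_label for inst in instances]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise EvaluationError("cross-validation needs both classes present")
    min_count = min(labels.count(c) for c in classes)
    if k != len(instances) and k > min_count:
        raise EvaluationError(
            f"k={k} exceeds the minority class count {min_count}")
    itemized = [itemize(inst, scheme) for inst in instances]
    y = np.array(labels)
    if k == len(instances):   # leave-one-out: stratification is vacuous
        splits = [(np.delete(np.arange(k), i), np.array([i]))
                  for i in range(k)]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(len(y)), y)
    per_fold: list[MetricEntry] = []
    pooled = ConfusionCounts()
    oof: list[Optional[str]] = [None] * len(instances)
    for fold, (tr, te) in enumerate(splits):
        train = [itemized[i] for i in tr]
        if balance:
            train = balance_classes(train, seed=seed + fold)
        store = mine_cars(train, min_support, min_confidence,
                          max_antecedent_len, dataset_id=f"fold{fold}")
        clf = LazyClassifier(store, train, fallback_class=fallback_class)
        predicted = [clf.classify(itemized[i][0]).label for i in te]
        for i, p in zip(te, predicted):
            oof[i] = p
        truth = [labels[i] for i in te]
        counts = confusion_from_labels(truth, predicted, positive_class)
        per_fold.append(compute_metrics(counts))
        pooled = pooled + counts
    return MetricReport(per_fold, compute_metrics(pooled),
                        aggregate_weighted(per_fold), predictions=oof)
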