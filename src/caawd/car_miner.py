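"""Class association rule (CAR) mining over behavior-instance itemsets.

A completed, labeled behavior instance is itemized into a transaction of
``attribute=value`` items (time bin, object, location, activity, one
item per distinct sub-activity, and a binned duration) plus its class
label.  CARs are rules ``antecedent -> class`` whose joint relative
support ``|antecedent ∪ class| / |D|`` meets a deliberately low minimum
support θ′ and whose confidence meets a minimum.  Low θ′ is the point:
infrequent but genuine routine fragments must survive into the rule
base, because the downstream lazy classifier prunes only contradicted
rules rather than low-support ones.

Mining is FP-growth over the feature items, with each tree node carrying
per-class counts so that rules for every class fall out of a single
pass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Mapping, Optional, Sequence

from .cdea import BehaviorInstance, TimeDiscretization, UNDETERMINED, parse_clock

FORMAT_VERSION = 1

ATTRIBUTES = ("time_bin", "object", "location", "sub_activity",
              "activity", "duration_bin")

Item = tuple[str, str]  # (attribute, value)


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class ItemizationScheme:
    """How instance fields become items: time bins plus duration bins."""

    time: TimeDiscretization = TimeDiscretization(60)
    duration_bin_minutes: int = 15

    def duration_label(self, minutes: int) -> str:
        w = self.duration_bin_minutes
        lo = (minutes // w) * w
        return f"[{lo},{lo + w})"


def itemize(instance: BehaviorInstance,
            scheme: ItemizationScheme | None = None,
            ) -> tuple[frozenset[Item], str]:
    """Convert one complete labeled instance into (itemset, class label).

    One item per populated attribute; each distinct sub-activity is its
    own item; duration is binned.  Instances with undetermined duration
    cannot be itemized.
    """
    scheme = scheme or ItemizationScheme()
    if instance.duration_minutes is UNDETERMINED:
        raise MiningError(
            f"cannot itemize {instance.activity} at {instance.start_time}: "
            "duration undetermined")
    items = {
        ("time_bin", instance.time_bin),
        ("object", instance.object),
        ("location", instance.location),
        ("activity", instance.activity),
        ("duration_bin", scheme.duration_label(instance.duration_minutes)),
    }
    items.discard(("object", ""))
    items.discard(("location", ""))
    for sa in instance.sub_activities:
        items.add(("sub_activity", sa))
    return frozenset(items), instance.class_label


def de_itemize(itemset: frozenset[Item], label: str) -> dict:
    """Recover the populated instance fields from an itemset (up to binning)."""
    fields: dict = {"sub_activities": [], "class_label": label}
    for attr, value in sorted(itemset):
        if attr == "sub_activity":
            fields["sub_activities"].append(value)
        else:
            fields[attr] = value
    return fields


def support(itemset: Iterable[Item],
            dataset: Sequence[frozenset[Item]]) -> float:
    """Relative support θ: fraction of transactions containing ``itemset``."""
    if not dataset:
        raise MiningError("support over an empty dataset is undefined")
    query = frozenset(itemset)
    return sum(1 for t in dataset if query <= t) / len(dataset)


@dataclass(frozen=True)
class CAR:
    """A class association rule ``antecedent -> consequent``.

    ``support`` is the joint relative support of antecedent and class;
    ``confidence`` is joint support over antecedent support.
    ``information_gain`` is filled lazily by the classifier.
    """

    antecedent: frozenset[Item]
    consequent: str
    support: float
    confidence: float
    information_gain: Optional[float] = None

    def key(self) -> tuple:
        return (tuple(sorted(f"{a}={v}" for a, v in self.antecedent)),
                self.consequent)

    def to_dict(self) -> dict:
        return {
            "antecedent": sorted(f"{a}={v}" for a, v in self.antecedent),
            "class": self.consequent,
            "support": self.support,
            "confidence": self.confidence,
            "information_gain": self.information_gain,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CAR":
        ant = frozenset(tuple(s.split("=", 1)) for s in d["antecedent"])
        return cls(ant, d["class"], d["support"], d["confidence"],
                   d.get("information_gain"))


@dataclass
class CARStore:
    rules: list[CAR] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rules:
            k = r.key()
            if k in seen:
                raise MiningError(f"duplicate rule {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


# ---------------------------------------------------------------------------
# FP-growth with per-class counts
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("item", "counts", "parent", "children", "link")

    def __init__(self, item, n_classes, parent):
        self.item = item
        self.counts = [0] * n_classes
        self.parent = parent
        self.children: dict = {}
        self.link: Optional[_Node] = None


def _build_tree(transactions, weights, order, n_classes):
    """Build an FP-tree; ``weights`` is a per-transaction class-count vector."""
    root = _Node(None, n_classes, None)
    header: dict = {}
    for trans, w in zip(transactions, weights):
        items = sorted((i for i in trans if i in order), key=order.__getitem__)
        node = root
        for it in items:
            child = node.children.get(it)
            if child is None:
                child = _Node(it, n_classes, node)
                node.children[it] = child
                child.link = header.get(it)
                header[it] = child
            for c in range(n_classes):
                child.counts[c] += w[c]
            node = child
    return root, header


def _fp_mine(transactions, weights, minsup_count, n_classes, max_len,
             suffix, out):
    # item -> total and per-class counts at this conditional level
    totals: dict = {}
    for trans, w in zip(transactions, weights):
        tw = sum(w)
        if tw == 0:
            continue
        for it in trans:
            if it not in totals:
                totals[it] = [0] * n_classes
            cc = totals[it]
            for c in range(n_classes):
                cc[c] += w[c]
    frequent = {it: cc for it, cc in totals.items()
                if sum(cc) >= minsup_count}
    if not frequent:
        return
    # global-frequency order, ties broken lexicographically for determinism
    order = {it: rank for rank, it in enumerate(
        sorted(frequent, key=lambda it: (-sum(frequent[it]), it)))}
    root, header = _build_tree(transactions, weights, order, n_classes)
    # mine suffixes from least frequent upward
    for it in sorted(order, key=order.__getitem__, reverse=True):
        counts = frequent[it]
        pattern = suffix | {it}
        out[frozenset(pattern)] = tuple(counts)
        if len(pattern) >= max_len:
            continue
        # conditional pattern base: prefix paths above each occurrence
        cond_trans, cond_weights = [], []
        node = header[it]
        while node is not None:
            path = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                cond_trans.append(path)
                cond_weights.append(list(node.counts))
            node = node.link
        if cond_trans:
            _fp_mine(cond_trans, cond_weights, minsup_count, n_classes,
                     max_len, pattern, out)


def frequent_itemsets(transactions: Sequence[frozenset[Item]],
                      labels: Sequence[str],
                      min_support: float,
                      max_len: int = 7,
                      ) -> tuple[dict[frozenset, tuple], list[str]]:
    """All feature itemsets with total support >= min_support, with
    per-class match counts.  Returns (itemset -> class counts, class order)."""
    n = len(transactions)
    classes = sorted(set(labels))
    idx = {c: i for i, c in enumerate(classes)}
    minsup_count = max(1, math.ceil(min_support * n - 1e-9))
    weights = []
    for lab in labels:
        w = [0] * len(classes)
        w[idx[lab]] = 1
        weights.append(w)
    out: dict = {}
    _fp_mine([list(t) for t in transactions], weights, minsup_count,
             len(classes), max_len, frozenset(), out)
    return out, classes


def mine_cars(dataset: Sequence[tuple[frozenset[Item], str]],
              min_support: float = 0.01,
              min_confidence: float = 0.5,
              max_antecedent_len: int = 7,
              dataset_id: str = "unnamed",
              mined_at: str | None = None,
              ) -> CARStore:
    """Mine the CAR base from itemized labeled instances.

    A rule ``A -> c`` is kept iff ``support(A ∪ {c}) >= min_support`` and
    ``confidence = support(A ∪ {c}) / support(A) >= min_confidence``.
    Anti-monotone pruning happens on the antecedent's total support,
    which upper-bounds every class-joint support.
    """
    if not 0 < min_support <= 1:
        raise MiningError(f"min_support must be in (0, 1], got {min_support}")
    if not 0 <= min_confidence <= 1:
        raise MiningError(
            f"min_confidence must be in [0, 1], got {min_confidence}")
    if not dataset:
        raise MiningError("cannot mine an empty dataset")
    transactions = [t for t, _ in dataset]
    labels = [lab for _, lab in dataset]
    if len(set(labels)) < 2:
        import logging
        logging.getLogger(__name__).warning(
            "single-class dataset: rules for the absent class are "
            "vacuously absent")
    n = len(dataset)
    itemsets, classes = frequent_itemsets(
        transactions, labels, min_support, max_antecedent_len)
    minsup_count = max(1, math.ceil(min_support * n - 1e-9))
    rules: list[CAR] = []
    for ant, counts in itemsets.items():
        total = sum(counts)
        for c, cnt in zip(classes, counts):
            if cnt >= minsup_count and cnt / total >= min_confidence:
                rules.append(CAR(ant, c, cnt / n, cnt / total))
    rules.sort(key=lambda r: r.key())
    return CARStore(rules, provenance={
        "dataset_id": dataset_id,
        "n_instances": n,
        "min_support": min_support,
        "min_confidence": min_confidence,
        "max_antecedent_len": max_antecedent_len,
        "mined_at": (mined_at if mined_at is not None else
                     datetime.now(timezone.utc).isoformat(timespec="seconds")),
    })


def save_cars(store: CARStore, path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "provenance": store.provenance,
        "rules": [r.to_dict() for r in store.rules],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_cars(path) -> CARStore:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise MiningError(
            f"rule store format version {version!r} not supported "
            f"(expected {FORMAT_VERSION})")
    rules = [CAR.from_dict(d) for d in payload["rules"]]
    return CARStore(rules, provenance=payload.get("provenance", {}))
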