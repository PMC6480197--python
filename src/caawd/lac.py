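"""Lazy associative classification with information-gain rule ranking.

Instead of committing to a global rule list at training time, the
classifier defers to query time: the stored CAR base is *projected*
onto the test instance (only rules whose antecedent is contained in the
test itemset survive), partitioned into *used* / *sparse* / *wrong*
sets, the wrong rules are lazily pruned, and the surviving rules are
ranked by the information gain their antecedent carries about the class
on the training data.  The top-ranked used rule classifies; sparse
rules are consulted when no used rule applies.  An empty projection
means the instance resembles no learned routine fragment at all and is
classified with a configurable fallback (``Abnormal`` by default: total
deviation from routine is itself the signal).

Rule partition semantics, made operational:

* **wrong** -- among training instances matching the rule's antecedent,
  the majority class differs from the rule's consequent;
* **used** -- not wrong, and the top-ranked applicable rule for at
  least one training instance;
* **sparse** -- the remainder: never a winner on training, but
  legitimate for test instances that used rules do not cover.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .car_miner import CAR, CARStore, Item

logger = logging.getLogger(__name__)

ABNORMAL_FALLBACK = "Abnormal"
NO_MATCH_REASON = "no matching routine pattern"


def entropy(counts: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy, in bits, of a class-count distribution.

    ``0 * log2(0)`` contributes zero; a pure distribution has entropy 0
    and a uniform one over k classes has log2(k).
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if any(v < 0 for v in values):
        raise ValueError("negative class counts")
    total = float(sum(values))
    if total <= 0:
        raise ValueError("at least one count must be positive")
    h = 0.0
    for v in values:
        if v > 0:
            p = v / total
            h -= p * math.log2(p)
    return h


def information_gain(antecedent: Iterable[Item],
                     dataset: Sequence[tuple[frozenset[Item], str]]) -> float:
    """IG of the binary event "instance matches the antecedent" about the class.

    ``IG = H(C) - sum_a P(a) H(C | a)`` over a in {match, no-match},
    computed against the labeled training data.  An antecedent matching
    zero instances carries no information; its IG is defined as 0.
    """
    ant = frozenset(antecedent)
    labels = [lab for _, lab in dataset]
    classes = sorted(set(labels))
    match_counts = {c: 0 for c in classes}
    miss_counts = {c: 0 for c in classes}
    for itemset, lab in dataset:
        (match_counts if ant <= itemset else miss_counts)[lab] += 1
    n_match = sum(match_counts.values())
    n = len(dataset)
    if n_match == 0:
        logger.warning("antecedent %s matches no training instance; IG := 0",
                       sorted(ant))
        return 0.0
    h_c = entropy([labels.count(c) for c in classes])
    h_cond = (n_match / n) * entropy(list(match_counts.values()))
    if n_match < n:
        h_cond += ((n - n_match) / n) * entropy(list(miss_counts.values()))
    return max(0.0, h_c - h_cond)


@dataclass
class RulePartition:
    used: list[CAR] = field(default_factory=list)
    sparse: list[CAR] = field(default_factory=list)
    wrong: list[CAR] = field(default_factory=list)

    def sizes(self) -> dict:
        return {"used": len(self.used), "sparse": len(self.sparse),
                "wrong": len(self.wrong)}


@dataclass
class Projection:
    """The stored rules applicable to one test instance, ranked."""

    test_itemset: frozenset[Item]
    rules: list[CAR]          # ranked best-first
    gains: list[float]


@dataclass
class ClassificationResult:
    label: str
    rule: Optional[CAR]
    information_gain: Optional[float]
    partition: RulePartition
    reason: str = ""


def _rank_key(rule: CAR, gain: float) -> tuple:
    """Total deterministic order: IG, then confidence, support, antecedent
    length (longer first), then lexicographic antecedent / consequent."""
    lex = tuple(sorted(f"{a}={v}" for a, v in rule.antecedent))
    return (-gain, -rule.confidence, -rule.support, -len(rule.antecedent),
            lex, rule.consequent)


class LazyClassifier:
    """CAR store bound to its training data, with cached IG and partitions.

    Information gain is a property of (rule, training data), so it is
    computed once per rule here and reused across every projection.
    """

    def __init__(self, store: CARStore,
                 training: Sequence[tuple[frozenset[Item], str]],
                 fallback_class: str = ABNORMAL_FALLBACK,
                 sparse_policy: str = "fallback-only") -> None:
        if sparse_policy not in ("fallback-only", "best-rank"):
            raise ValueError(f"unknown sparse policy {sparse_policy!r}")
        self.store = store
        self.training = list(training)
        self.fallback_class = fallback_class
        self.sparse_policy = sparse_policy
        self._prepare()

    # -- training-time caches ------------------------------------------------
    def _prepare(self) -> None:
        rules = list(self.store.rules)
        train_sets = [t for t, _ in self.training]
        labels = [lab for _, lab in self.training]
        classes = sorted(set(labels))
        cls_idx = {c: i for i, c in enumerate(classes)}
        y = np.array([cls_idx[lab] for lab in labels])
        n = len(train_sets)
        n_cls = len(classes)

        # vocabulary over training items; antecedent items outside it can
        # never match a training instance
        vocab: dict[Item, int] = {}
        for t in train_sets:
            for it in t:
                vocab.setdefault(it, len(vocab))
        inst = np.zeros((n, max(len(vocab), 1)), dtype=bool)
        for i, t in enumerate(train_sets):
            for it in t:
                inst[i, vocab[it]] = True

        match = np.zeros((len(rules), n), dtype=bool)
        for r_i, rule in enumerate(rules):
            idx = [vocab.get(it) for it in rule.antecedent]
            if any(j is None for j in idx):
                continue
            if idx:
                match[r_i] = inst[:, idx].all(axis=1)
            else:
                match[r_i] = True

        class_totals = np.bincount(y, minlength=n_cls).astype(float)
        h_c = entropy(class_totals)
        gains = np.zeros(len(rules))
        wrong = np.zeros(len(rules), dtype=bool)
        for r_i, rule in enumerate(rules):
            m = match[r_i]
            n_match = int(m.sum())
            if n_match == 0:
                continue
            mc = np.bincount(y[m], minlength=n_cls).astype(float)
            h_cond = (n_match / n) * entropy(mc)
            if n_match < n:
                h_cond += ((n - n_match) / n) * entropy(class_totals - mc)
            gains[r_i] = max(0.0, h_c - h_cond)
            # wrong: majority class among matches contradicts the consequent
            ci = cls_idx.get(rule.consequent)
            own = mc[ci] if ci is not None else 0.0
            if own < mc.max():
                wrong[r_i] = True

        order = sorted(range(len(rules)),
                       key=lambda i: _rank_key(rules[i], gains[i]))
        rank = np.empty(len(rules), dtype=int)
        for pos, r_i in enumerate(order):
            rank[r_i] = pos

        # used: best-ranked non-wrong applicable rule for >= 1 training row
        used = np.zeros(len(rules), dtype=bool)
        ok = ~wrong
        for i in range(n):
            applicable = np.flatnonzero(match[:, i] & ok)
            if applicable.size:
                used[applicable[np.argmin(rank[applicable])]] = True

        self.rules = rules
        self.gains = gains
        self.wrong_mask = wrong
        self.used_mask = used
        self.rank = rank
        self._h_c = h_c

    # -- query time ----------------------------------------------------------
    def project(self, test_itemset: frozenset[Item]) -> Projection:
        """Rules whose antecedent is contained in the test itemset, ranked."""
        idx = [i for i, r in enumerate(self.rules)
               if r.antecedent <= test_itemset]
        idx.sort(key=lambda i: self.rank[i])
        return Projection(test_itemset,
                          [self.rules[i] for i in idx],
                          [self.gains[i] for i in idx])

    def _indices(self, projection: Projection) -> list[int]:
        by_key = {r.key(): i for i, r in enumerate(self.rules)}
        return [by_key[r.key()] for r in projection.rules]

    def partition(self, projection: Projection) -> RulePartition:
        """Split a projection into used / sparse / wrong (pairwise disjoint,
        union = projection)."""
        part = RulePartition()
        for r, i in zip(projection.rules, self._indices(projection)):
            if self.wrong_mask[i]:
                part.wrong.append(r)
            elif self.used_mask[i]:
                part.used.append(r)
            else:
                part.sparse.append(r)
        return part

    def classify(self, test_itemset: frozenset[Item]) -> ClassificationResult:
        projection = self.project(test_itemset)
        part = self.partition(projection)
        idx = self._indices(projection)
        ok = [(r, i) for r, i in zip(projection.rules, idx)
              if not self.wrong_mask[i]]
        pick: Optional[tuple[CAR, int]] = None
        if self.sparse_policy == "best-rank":
            if ok:
                pick = min(ok, key=lambda ri: self.rank[ri[1]])
        else:
            used = [(r, i) for r, i in ok if self.used_mask[i]]
            pool = used or ok  # sparse rules only when no used rule applies
            if pool:
                pick = min(pool, key=lambda ri: self.rank[ri[1]])
        if pick is None:
            reason = (NO_MATCH_REASON if not projection.rules
                      else "all projected rules contradicted by training")
            return ClassificationResult(self.fallback_class, None, None,
                                        part, reason)
        rule, i = pick
        winning = CAR(rule.antecedent, rule.consequent, rule.support,
                      rule.confidence, float(self.gains[i]))
        return ClassificationResult(winning.consequent, winning,
                                    winning.information_gain, part)

    def classify_many(self, itemsets: Iterable[frozenset[Item]]
                      ) -> list[ClassificationResult]:
        return [self.classify(t) for t in itemsets]


# ---------------------------------------------------------------------------
# Functional entry points mirroring the operation surface
# ---------------------------------------------------------------------------

def project(store: CARStore, test_itemset: frozenset[Item],
            training: Sequence[tuple[frozenset[Item], str]] | None = None,
            ) -> Projection:
    """Project the rule base onto a test itemset.

    Without training data the projection is ranked by (confidence,
    support) only; with it, by cached information gain.
    """
    if training is not None:
        return LazyClassifier(store, training).project(test_itemset)
    rules = [r for r in store.rules if r.antecedent <= test_itemset]
    rules.sort(key=lambda r: _rank_key(r, 0.0))
    return Projection(test_itemset, rules, [0.0] * len(rules))


def partition_rules(projection: Projection,
                    training: Sequence[tuple[frozenset[Item], str]],
                    ) -> RulePartition:
    """Partition a projected rule set against labeled training data.

    Self-contained variant: "used" is judged within the projected rules
    themselves (the top-ranked non-wrong rule applicable to at least one
    training instance).
    """
    sub_store = CARStore(list(projection.rules))
    clf = LazyClassifier(sub_store, training)
    return clf.partition(clf.project(projection.test_itemset))


def classify(test_itemset: frozenset[Item], store: CARStore,
             training: Sequence[tuple[frozenset[Item], str]],
             fallback_class: str = ABNORMAL_FALLBACK,
             sparse_policy: str = "fallback-only") -> ClassificationResult:
    """One-shot classification of a single test itemset."""
    return LazyClassifier(store, training, fallback_class,
                          sparse_policy).classify(test_itemset)
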