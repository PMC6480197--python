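"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(plain loops, no trees, no caching, no vectorization) so it shares no
code path with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

from caawd.cdea import ON, OFF, BehaviorInstance, discretize_time


# ---------------------------------------------------------------------------
# Interval-pairing extraction oracle
# ---------------------------------------------------------------------------

def pair_extract(events, smap, scheme):
    """Pair every main ON with its next OFF and gather enclosed sub events."""
    instances = []
    for sid, main in smap.main.items():
        ons = [e.timestamp for e in events if e.sensor_id == sid and e.state == ON]
        offs = [e.timestamp for e in events if e.sensor_id == sid and e.state == OFF]
        oi = 0
        for on in ons:
            while oi < len(offs) and offs[oi] < on:
                oi += 1
            if oi >= len(offs):
                break
            off = offs[oi]
            oi += 1
            subs = []
            for e in events:
                if (e.state == ON and e.sensor_id in smap.sub
                        and smap.sub[e.sensor_id].parent_id == sid
                        and on <= e.timestamp < off):
                    name = smap.sub[e.sensor_id].sub_activity
                    if name not in subs:
                        subs.append(name)
            instances.append(BehaviorInstance(
                start_time=on,
                time_bin=discretize_time(on, scheme),
                object=main.object, location=main.location,
                sub_activities=tuple(subs), activity=main.activity,
                duration_minutes=int((off - on).total_seconds() // 60)))
    instances.sort(key=lambda i: i.start_time)
    return instances


# ---------------------------------------------------------------------------
# Exhaustive CAR enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_cars(dataset, min_support, min_confidence, max_len=7):
    """Every antecedent subset of every transaction, counted by brute force.

    Returns {(sorted antecedent tuple, class): (support, confidence)}.
    """
    n = len(dataset)
    counts = Counter()          # antecedent -> per-class counts
    totals = Counter()          # antecedent -> total matches
    seen = set()
    for trans, _ in dataset:
        items = sorted(trans)
        for k in range(1, min(len(items), max_len) + 1):
            for combo in itertools.combinations(items, k):
                seen.add(combo)
    for combo in seen:
        ant = set(combo)
        for trans, lab in dataset:
            if ant <= trans:
                counts[(combo, lab)] += 1
                totals[combo] += 1
    rules = {}
    for (combo, lab), cnt in counts.items():
        sup = cnt / n
        conf = cnt / totals[combo]
        if cnt >= min_support * n - 1e-9 and conf >= min_confidence - 1e-12:
            key = (tuple(f"{a}={v}" for a, v in combo), lab)
            rules[key] = (sup, conf)
    return rules


def brute_support(itemset, dataset):
    query = set(itemset)
    return sum(1 for t in dataset if query <= t) / len(dataset)


# ---------------------------------------------------------------------------
# Entropy / information gain by direct contingency table
# ---------------------------------------------------------------------------

def table_entropy(values):
    total = sum(values)
    h = 0.0
    for v in values:
        if v:
            h -= (v / total) * math.log2(v / total)
    return h


def table_ig(antecedent, dataset):
    ant = set(antecedent)
    classes = sorted({lab for _, lab in dataset})
    m = {c: 0 for c in classes}
    o = {c: 0 for c in classes}
    for t, lab in dataset:
        (m if ant <= t else o)[lab] += 1
    n = len(dataset)
    nm = sum(m.values())
    if nm == 0:
        return 0.0
    prior = [sum(1 for _, lab in dataset if lab == c) for c in classes]
    h = table_entropy(prior)
    cond = (nm / n) * table_entropy(list(m.values()))
    if nm < n:
        cond += ((n - nm) / n) * table_entropy(list(o.values()))
    return max(0.0, h - cond)


# ---------------------------------------------------------------------------
# Plain rule-scoring classifier oracle
# ---------------------------------------------------------------------------

def _sort_key(rule, gain):
    lex = tuple(sorted(f"{a}={v}" for a, v in rule.antecedent))
    return (-gain, -rule.confidence, -rule.support, -len(rule.antecedent),
            lex, rule.consequent)


def brute_classify(test_itemset, rules, training, fallback="Abnormal"):
    """Score every stored rule with plain loops and classify the test.

    Re-derives, independently of the package: per-rule IG over training,
    the wrong set (majority disagreement), the used set (best applicable
    rule per training row) and the final used-then-sparse selection.
    """
    gains = [table_ig(r.antecedent, training) for r in rules]
    wrong = []
    for r in rules:
        match = [lab for t, lab in training if set(r.antecedent) <= t]
        if match:
            tally = Counter(match)
            top = max(tally.values())
            wrong.append(tally.get(r.consequent, 0) < top)
        else:
            wrong.append(False)
    used = set()
    for t, _ in training:
        applicable = [i for i, r in enumerate(rules)
                      if set(r.antecedent) <= t and not wrong[i]]
        if applicable:
            used.add(min(applicable,
                         key=lambda i: _sort_key(rules[i], gains[i])))
    projected = [i for i, r in enumerate(rules)
                 if set(r.antecedent) <= test_itemset]
    ok = [i for i in projected if not wrong[i]]
    pool = [i for i in ok if i in used] or ok
    if not pool:
        return fallback
    best = min(pool, key=lambda i: _sort_key(rules[i], gains[i]))
    return rules[best].consequent


# ---------------------------------------------------------------------------
# Caregiver range-check oracle
# ---------------------------------------------------------------------------

def brute_context_check(instances, context):
    """Literal re-derivation of the per-instance contextual verdicts.

    Walks the day-ordered instances keeping per-(activity, day) counts;
    every instance increments its count; Abnormal-classified ones are
    checked against the three inclusive ranges with AND logic.  Returns
    the final class per instance.
    """
    counts = {}
    finals = []
    for inst in instances:
        key = (inst.activity, inst.start_time.date())
        counts[key] = counts.get(key, 0) + 1
        if inst.class_label != "Abnormal":
            finals.append(inst.class_label)
            continue
        if inst.activity not in context:
            finals.append("Abnormal")
            continue
        c = context[inst.activity]
        ok = True
        if c.duration_range is not None:
            d = inst.duration_minutes
            ok = ok and d is not None and c.duration_range[0] <= d <= c.duration_range[1]
        if c.start_time_range is not None:
            st = inst.start_time.time()
            ok = ok and c.start_time_range[0] <= st <= c.start_time_range[1]
        if c.frequency_range is not None:
            ok = ok and c.frequency_range[0] <= counts[key] <= c.frequency_range[1]
        finals.append("Normal" if ok else "Abnormal")
    return finals
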