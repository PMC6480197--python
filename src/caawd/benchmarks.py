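"""Reproducible synthetic benchmarks for the full wellness stack.

Two study designs are packaged:

* :func:`wellness_benchmark` -- a cohort of simulated subjects, each a
  multi-day routine with a fixed fraction of injected anomalies, for
  cross-validated classifier evaluation (per-subject accuracy,
  precision, recall, F).

* :func:`contextual_benchmark` -- a balanced validation set of 2000
  behavior instances (1000 normal, 1000 abnormal, and of the abnormal
  half contextually normal under the caregiver context and half
  contextually abnormal) exercising the post-classification context
  check.  The perturbation windows are chosen so the contextual verdict
  of every perturbed instance is structural -- inside or outside the
  caregiver ranges by construction -- which makes the 500/500 split
  invariant to the seed while the individual magnitudes still vary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

from .car_miner import ItemizationScheme
from .cdea import ABNORMAL, NORMAL, BehaviorInstance, extract_instances, parse_clock
from .context_validator import CaregiverContext, default_caregiver_context
from .synthetic_home import (AnomalySpec, Episode, PerturbedStream,
                             RoutineProfile, SimulatedStream, default_profile,
                             generate_routine, inject_anomalies)


class BenchmarkError(ValueError):
    pass


def labeled_instances(stream: PerturbedStream | SimulatedStream,
                      scheme: ItemizationScheme | None = None,
                      ) -> tuple[list[BehaviorInstance], list[Optional[bool]]]:
    """Extract behavior instances from a simulated stream and attach the
    generator's ground-truth labels and contextual truth.

    Instances come back through the real extraction sweep (not copied
    from the schedule), then are matched to episodes by activity and
    start time.
    """
    scheme = scheme or ItemizationScheme()
    raw = extract_instances(stream.events, stream.sensor_map, scheme.time)
    by_key = {(e.activity, e.start): i for i, e in enumerate(stream.episodes)}
    if len(raw) != len(stream.episodes):
        raise BenchmarkError(
            f"extracted {len(raw)} instances from {len(stream.episodes)} "
            "scheduled episodes")
    labels = stream.labels
    truth = getattr(stream, "contextual_truth", None) or [None] * len(raw)
    out_inst, out_truth = [], []
    for inst in raw:
        i = by_key.get((inst.activity, inst.start_time))
        if i is None:
            raise BenchmarkError(
                f"extracted instance {inst.activity} at {inst.start_time} "
                "matches no scheduled episode")
        out_inst.append(inst.with_label(labels[i]))
        out_truth.append(truth[i])
    return out_inst, out_truth


# ---------------------------------------------------------------------------
# Cohort benchmark for classifier evaluation
# ---------------------------------------------------------------------------

#: Target windows for per-activity anomaly perturbations: activity ->
#: (kind, target window).  Duration targets are absolute minutes; start
#: targets are clock windows.  Each anomaly type is a *canonical*
#: deviation -- sleeping ~2.5 h longer than usual, nocturnal toileting,
#: a near-zero walk -- rather than a diffuse smear: its window sits in a
#: characteristic off-routine position narrow enough to fall inside one
#: itemization bin that routine behavior never occupies.
_ANOMALY_TARGETS = {
    "Sleeping": ("duration", (645, 659)),
    "Toileting": ("start", ("02:05", "03:55")),
    "Showering": ("duration", (61, 74)),
    "Breakfast": ("start", ("06:05", "06:55")),
    "Lunch": ("duration", (90, 104)),
    "Dinner": ("duration", (90, 104)),
    "Snack": ("start", ("00:05", "00:55")),
    "TV": ("duration", (210, 224)),
    "Grooming": ("start", ("01:05", "01:55")),
    "Leaving": ("duration", (2, 10)),
}


def _minute(ep: Episode) -> int:
    return ep.start.hour * 60 + ep.start.minute


def _anomaly_spec_for(ep: Episode, rng, claimed: dict) -> AnomalySpec:
    kind, window = _ANOMALY_TARGETS[ep.activity]
    if kind == "duration":
        lo, hi = window
        target = int(rng.integers(lo, hi + 1))
        return AnomalySpec("duration_shift", ep.activity,
                           magnitude=target - ep.duration, at=ep.start)
    lo = _clock_minutes(window[0])
    hi = _clock_minutes(window[1])
    # same-activity occurrences moved into one night window must stay
    # disjoint; claim minute intervals per (activity, day)
    key = (ep.activity, ep.day)
    taken = claimed.setdefault(key, [])
    for _ in range(500):
        target = int(rng.integers(lo, hi + 1))
        end = target + ep.duration + 1
        if all(end <= a or target >= b for a, b in taken):
            break
    else:
        raise BenchmarkError(
            f"cannot place shifted {ep.activity} occurrence on day {ep.day}")
    taken.append((target, end))
    return AnomalySpec("start_time_shift", ep.activity,
                       magnitude=target - _minute(ep), at=ep.start)


def _clock_minutes(text: str) -> int:
    t = parse_clock(text)
    return t.hour * 60 + t.minute


@dataclass
class SubjectData:
    subject: str
    instances: list[BehaviorInstance]
    stream: PerturbedStream

    @property
    def n_abnormal(self) -> int:
        return sum(i.class_label == ABNORMAL for i in self.instances)


def wellness_benchmark(n_subjects: int = 10, days: int = 14,
                       anomaly_rate: float = 0.2, seed: int = 0,
                       scheme: ItemizationScheme | None = None,
                       ) -> list[SubjectData]:
    """Simulated cohort: each subject is a seeded multi-day routine with
    ``anomaly_rate`` of its behavior instances perturbed in place.

    The rate is applied per activity (stratified), so every ADL carries
    the same anomaly incidence; drawing the perturbed set uniformly over
    all episodes would leave the rarer activities with wildly varying
    anomaly rates across subjects.
    """
    if not 0 < anomaly_rate < 1:
        raise BenchmarkError("anomaly_rate must be in (0, 1)")
    subjects = []
    for s in range(n_subjects):
        sub_seed = (seed * 9973 + s * 101 + 17) % (2 ** 31)
        profile = default_profile(days=days, seed=sub_seed)
        stream = generate_routine(profile)
        rng = np.random.default_rng(sub_seed + 1)
        by_act: dict[str, list[int]] = {}
        for i, ep in enumerate(stream.episodes):
            by_act.setdefault(ep.activity, []).append(i)
        chosen: list[int] = []
        for act in sorted(by_act):
            idx = by_act[act]
            n_act = int(round(anomaly_rate * len(idx)))
            chosen.extend(rng.choice(idx, size=n_act, replace=False))
        claimed: dict = {}
        specs = [_anomaly_spec_for(stream.episodes[i], rng, claimed)
                 for i in sorted(chosen)]
        perturbed = inject_anomalies(stream, specs, context=None,
                                     seed=sub_seed + 2)
        instances, _ = labeled_instances(perturbed, scheme)
        subjects.append(SubjectData(f"Subject-{s + 1}", instances, perturbed))
    return subjects


# ---------------------------------------------------------------------------
# Contextual-validation benchmark
# ---------------------------------------------------------------------------

# per-day perturbation slots: (activity, occurrence role, kind, target window,
# expected contextual verdict).  Windows sit inside the caregiver ranges for
# the contextually-normal slots and outside them for the contextually-abnormal
# ones, while always deviating from the routine envelope.
_CTX_NORMAL_SLOTS = (
    ("Leaving", "only", "duration", (46, 59)),
    ("Breakfast", "only", "start", ("10:00", "10:25")),
    ("Lunch", "only", "start", ("14:35", "15:25")),
    ("Toileting", "last", "start", ("22:05", "22:55")),
)
_CTX_ABNORMAL_SLOTS = (
    ("Sleeping", "only", "duration", (780, 900)),
    ("Showering", "only", "duration", (120, 200)),
    ("Dinner", "only", "start", ("17:05", "17:55")),
    ("Toileting", "first", "start", ("01:05", "01:55")),
)


def _contextual_profile(days: int, seed: int) -> RoutineProfile:
    """Fixed-frequency variant of the default profile: exactly 16
    instances per day (toileting 6x, grooming 2x, everything else 1x)."""
    base = default_profile(days=days, seed=seed)
    acts = []
    for a in base.activities:
        if a.activity == "Toileting":
            a = replace(a, daily_frequency_window=(6, 6))
        elif a.activity == "Grooming":
            a = replace(a, daily_frequency_window=(2, 2),
                        start_time_window=(parse_clock("07:50"),
                                           parse_clock("08:45")))
        acts.append(a)
    return RoutineProfile(tuple(acts), days=days, seed=seed)


def _slot_episode(stream: SimulatedStream, day: int, activity: str,
                  role: str) -> Episode:
    eps = sorted((e for e in stream.episodes
                  if e.activity == activity and e.day == day),
                 key=lambda e: e.start)
    if role == "first":
        return eps[0]
    if role == "last":
        return eps[-1]
    (ep,) = eps
    return ep


@dataclass
class ContextualBenchmark:
    instances: list[BehaviorInstance]        # ground-truth class labels set
    contextual_truth: list[Optional[bool]]   # aligned with instances
    context: CaregiverContext
    stream: PerturbedStream

    @property
    def n_abnormal(self) -> int:
        return sum(i.class_label == ABNORMAL for i in self.instances)

    @property
    def n_contextually_normal(self) -> int:
        return sum(bool(t) and i.class_label == ABNORMAL
                   for i, t in zip(self.instances, self.contextual_truth))


def contextual_benchmark(seed: int = 0,
                         n_normal: int = 1000,
                         n_abnormal: int = 1000,
                         n_contextually_normal: int = 500,
                         context: CaregiverContext | None = None,
                         scheme: ItemizationScheme | None = None,
                         ) -> ContextualBenchmark:
    """Balanced contextual-validation set.

    Builds a fixed 16-instance/day routine over ``(n_normal +
    n_abnormal) / 16`` days, perturbs exactly ``n_abnormal`` instances
    (``n_contextually_normal`` of them into windows that satisfy every
    caregiver range, the rest into windows that violate one), and
    returns the day-ordered extracted instances with ground truth.
    """
    total = n_normal + n_abnormal
    if total % 16:
        raise BenchmarkError("n_normal + n_abnormal must be a multiple of "
                             "16 (the fixed per-day instance count)")
    days = total // 16
    n_ctx_abnormal = n_abnormal - n_contextually_normal
    if n_contextually_normal > 4 * days or n_ctx_abnormal > 4 * days:
        raise BenchmarkError(
            f"at most {4 * days} contextually-normal and {4 * days} "
            "contextually-abnormal anomalies fit in this design")
    context = context or default_caregiver_context()
    profile = _contextual_profile(days=days, seed=(seed * 7919 + 3) % (2 ** 31))
    stream = generate_routine(profile)
    rng = np.random.default_rng(seed)

    specs: list[AnomalySpec] = []
    for slots, count, expect in ((_CTX_NORMAL_SLOTS, n_contextually_normal, True),
                                 (_CTX_ABNORMAL_SLOTS, n_ctx_abnormal, False)):
        pool = [(day, slot) for slot in slots for day in range(days)]
        order = rng.permutation(len(pool))[:count]
        for idx in sorted(order):
            day, (activity, role, kind, window) = pool[idx]
            ep = _slot_episode(stream, day, activity, role)
            if kind == "duration":
                lo, hi = window
                target = int(rng.integers(lo, hi + 1))
                specs.append(AnomalySpec(
                    "duration_shift", activity,
                    magnitude=target - ep.duration, at=ep.start,
                    contextually_normal=expect))
            else:
                lo, hi = _clock_minutes(window[0]), _clock_minutes(window[1])
                target = int(rng.integers(lo, hi + 1))
                specs.append(AnomalySpec(
                    "start_time_shift", activity,
                    magnitude=target - _minute(ep), at=ep.start,
                    contextually_normal=expect))

    perturbed = inject_anomalies(stream, specs, context=context,
                                 seed=(seed + 1) % (2 ** 31))
    instances, truth = labeled_instances(perturbed, scheme)
    bench = ContextualBenchmark(instances, truth, context, perturbed)
    if bench.n_abnormal != n_abnormal:
        raise BenchmarkError(
            f"composition error: {bench.n_abnormal} abnormal instances, "
            f"requested {n_abnormal}")
    if bench.n_contextually_normal != n_contextually_normal:
        raise BenchmarkError(
            f"composition error: {bench.n_contextually_normal} contextually "
            f"normal, requested {n_contextually_normal}")
    return bench
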