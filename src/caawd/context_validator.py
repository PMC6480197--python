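"""Caregiver-context validation of abnormal-classified behavior instances.

A caregiver supplies, per activity, up to three inclusive ranges: daily
frequency, duration (minutes) and start time (24 h clock).  An instance
the classifier flagged Abnormal is re-examined with AND logic: it is
reclassified Normal iff every *present* range contains the instance's
value.  Absent ranges pass vacuously (a caregiver who sets no start-time
window for toileting is not forbidding all start times).  Frequency is a
running per-calendar-day count, incremented for every observed instance
of the activity *before* the check, so the current instance counts
itself.

This captures the clinical reality that routine-derived rules lag
behind caregiver knowledge: an 11.5 h sleep deviates from an 8 h routine
but is unremarkable when bed rest up to 12 h is medically recommended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, time
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .cdea import ABNORMAL, NORMAL, BehaviorInstance, format_clock, parse_clock


class ContextError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityContext:
    """Caregiver ranges for one activity; any range may be absent (None)."""

    frequency_range: Optional[tuple[int, int]] = None
    duration_range: Optional[tuple[int, int]] = None       # minutes
    start_time_range: Optional[tuple[time, time]] = None   # never wraps midnight

    def __post_init__(self) -> None:
        for name, rng in (("frequency", self.frequency_range),
                          ("duration", self.duration_range),
                          ("start_time", self.start_time_range)):
            if rng is not None and rng[0] > rng[1]:
                raise ContextError(f"{name} range has min > max: {rng}")


class CaregiverContext:
    """Per-activity caregiver ranges (declarative input, never learned)."""

    def __init__(self, activities: Mapping[str, ActivityContext]) -> None:
        self.activities = dict(activities)

    def __contains__(self, activity: str) -> bool:
        return activity in self.activities

    def __getitem__(self, activity: str) -> ActivityContext:
        return self.activities[activity]

    def to_dict(self) -> dict:
        out = {}
        for act, c in self.activities.items():
            out[act] = {
                "frequency": list(c.frequency_range) if c.frequency_range else None,
                "duration_minutes": list(c.duration_range) if c.duration_range else None,
                "start_time": ([format_clock(c.start_time_range[0]),
                                format_clock(c.start_time_range[1])]
                               if c.start_time_range else None),
            }
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "CaregiverContext":
        acts = {}
        for act, c in d.items():
            st = c.get("start_time")
            acts[act] = ActivityContext(
                frequency_range=tuple(c["frequency"]) if c.get("frequency") else None,
                duration_range=tuple(c["duration_minutes"]) if c.get("duration_minutes") else None,
                start_time_range=(parse_clock(st[0]), parse_clock(st[1])) if st else None,
            )
        return cls(acts)

    @classmethod
    def from_file(cls, path) -> "CaregiverContext":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_caregiver_context() -> CaregiverContext:
    """Reference context for a single-resident elderly routine.

    Nightly sleep of 8-12 h starting 22:30-23:30, one or two daily walks
    of 30-60 min late morning to mid-afternoon, meals once a day in
    their usual windows, toileting 4-8 times and showering 1-3 times a
    day with no prescribed clock window.
    """
    hm = parse_clock
    return CaregiverContext({
        "Sleeping": ActivityContext((2, 3), (8 * 60, 12 * 60),
                                    (hm("22:30"), hm("23:30"))),
        "Leaving": ActivityContext((1, 2), (30, 60),
                                   (hm("10:30"), hm("15:30"))),
        "Toileting": ActivityContext((4, 8), (1, 10), None),
        "Breakfast": ActivityContext((1, 1), (15, 35),
                                     (hm("09:30"), hm("10:30"))),
        "Lunch": ActivityContext((1, 1), (25, 50),
                                 (hm("13:00"), hm("15:30"))),
        "Dinner": ActivityContext((1, 1), (25, 50),
                                  (hm("18:30"), hm("21:30"))),
        "Showering": ActivityContext((1, 3), (10, 15), None),
    })


@dataclass
class FrequencyState:
    """Running per-(activity, day) occurrence counts."""

    counts: dict[tuple[str, date], int] = field(default_factory=dict)

    def observe(self, instance: BehaviorInstance) -> int:
        """Increment the instance's (activity, day) count and return it."""
        key = (instance.activity, instance.day)
        self.counts[key] = self.counts.get(key, 0) + 1
        return self.counts[key]


@dataclass(frozen=True)
class Violation:
    attribute: str     # duration | start_time | frequency
    observed: object
    expected: tuple


def check_ranges(instance: BehaviorInstance, actx: ActivityContext,
                 frequency_count: int) -> list[Violation]:
    """Evaluate the three caregiver ranges; absent ranges pass vacuously.

    Membership is inclusive on both endpoints.
    """
    violations = []
    if actx.duration_range is not None:
        lo, hi = actx.duration_range
        d = instance.duration_minutes
        if d is None or not lo <= d <= hi:
            violations.append(Violation("duration", d, (lo, hi)))
    if actx.start_time_range is not None:
        lo, hi = actx.start_time_range
        st = instance.start_time.time()
        if not lo <= st <= hi:
            violations.append(
                Violation("start_time", format_clock(st),
                          (format_clock(lo), format_clock(hi))))
    if actx.frequency_range is not None:
        lo, hi = actx.frequency_range
        if not lo <= frequency_count <= hi:
            violations.append(Violation("frequency", frequency_count, (lo, hi)))
    return violations


def validate(instance: BehaviorInstance, ctx: CaregiverContext,
             freq: FrequencyState,
             no_context_policy: str = "abnormal",
             ) -> tuple[str, list[Violation], str]:
    """Re-examine one Abnormal-classified instance against the context.

    Returns (final class, violations, reason).  The frequency counter is
    incremented before the check, so the instance counts itself.
    """
    if instance.class_label != ABNORMAL:
        raise ContextError(
            "context validation applies to Abnormal-classified instances, "
            f"got {instance.class_label!r}")
    count = freq.observe(instance)
    if instance.activity not in ctx:
        if no_context_policy == "normal":
            return NORMAL, [], "no context defined"
        return ABNORMAL, [], "no context defined"
    violations = check_ranges(instance, ctx[instance.activity], count)
    if violations:
        return ABNORMAL, violations, "context range violated"
    return NORMAL, [], "all caregiver ranges satisfied"


@dataclass
class ValidationRecord:
    instance: BehaviorInstance
    final_class: str
    reclassified: bool
    violations: list[Violation]
    reason: str


@dataclass
class ValidationReport:
    records: list[ValidationRecord]

    @property
    def reclassified_count(self) -> int:
        return sum(r.reclassified for r in self.records)

    @property
    def final_labels(self) -> list[str]:
        return [r.final_class for r in self.records]

    def summary(self) -> dict:
        return {
            "n_instances": len(self.records),
            "n_abnormal_in": sum(
                r.instance.class_label == ABNORMAL for r in self.records),
            "reclassified_to_normal": self.reclassified_count,
            "final_abnormal": sum(
                r.final_class == ABNORMAL for r in self.records),
        }


def batch_validate(instances: Sequence[BehaviorInstance],
                   ctx: CaregiverContext,
                   no_context_policy: str = "abnormal",
                   ) -> ValidationReport:
    """Validate a day-ordered batch of classified instances.

    Normal-classified inputs pass through untouched but still advance
    the per-day frequency counters (the caregiver's frequency ranges
    refer to how often the activity happened, not how often it was
    flagged).  Only Abnormal-classified inputs get the range check.
    """
    times = [i.start_time for i in instances]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ContextError("instances must be ordered by start time "
                           "(frequency counting is day-stateful)")
    freq = FrequencyState()
    records = []
    for inst in instances:
        if inst.class_label == ABNORMAL:
            final, violations, reason = validate(
                inst, ctx, freq, no_context_policy)
            records.append(ValidationRecord(
                inst, final, final == NORMAL, violations, reason))
        else:
            freq.observe(inst)
            records.append(ValidationRecord(
                inst, inst.class_label, False, [], "not abnormal-classified"))
    return ValidationReport(records)


@dataclass
class AlarmRecord:
    """Caregiver notification describing one confirmed abnormal behavior."""

    activity: str
    location: str
    object: str
    start_time: str
    duration_minutes: Optional[int]
    violated: list[dict]
    description: str

    def to_json(self) -> str:
        return json.dumps(vars(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AlarmRecord":
        return cls(**json.loads(text))


def emit_alarm(instance: BehaviorInstance,
               violations: Sequence[Violation] = ()) -> AlarmRecord:
    """Build the caregiver alarm for a final-class-Abnormal instance.

    The description names the activity and every violated attribute with
    observed value and expected range; with no recorded range violation
    (the rule-based stage flagged it) the deviation is reported as a
    departure from the learned routine pattern.
    """
    if instance.class_label != ABNORMAL:
        raise ContextError("alarms are emitted only for Abnormal instances")
    violated = [{"attribute": v.attribute, "observed": v.observed,
                 "expected": list(v.expected)} for v in violations]
    where = f" in {instance.location}" if instance.location else ""
    if violations:
        parts = ", ".join(
            f"{v.attribute} {v.observed} outside expected "
            f"{v.expected[0]}-{v.expected[1]}" for v in violations)
        desc = (f"{instance.activity}{where} at "
                f"{instance.start_time:%Y-%m-%d %H:%M}: {parts}")
    else:
        desc = (f"{instance.activity}{where} at "
                f"{instance.start_time:%Y-%m-%d %H:%M} deviates from the "
                "learned routine pattern")
    return AlarmRecord(
        activity=instance.activity,
        location=instance.location,
        object=instance.object,
        start_time=instance.start_time.isoformat(timespec="minutes"),
        duration_minutes=instance.duration_minutes,
        violated=violated,
        description=desc,
    )
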