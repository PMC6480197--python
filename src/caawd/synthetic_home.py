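"""Seeded simulator of a single-resident four-room smart home.

Emulates the sensing setup the rest of the stack consumes: binary
main-activity sensors (door magnet, bed pressure, shower PIR, ...) and
sub-activity sensors (fridge, cabinet, cooktop, ...) attached to
household objects, firing ON/OFF as an elderly resident walks through a
multi-day routine of activities of daily living.  Every draw is taken
from an explicit per-activity window (start time, duration, daily
frequency), so ground truth is known by construction and every
downstream module is testable without any external dataset.

Anomaly injection perturbs scheduled activity episodes in four ways --
duration shifts (sleeping longer than usual), start-time shifts
(nocturnal toileting), frequency shifts (extra occurrences) and missing
activities (a day with zero leaving) -- and records, per perturbed
instance, both the behavioral label (Abnormal) and the *contextual*
ground truth: whether the perturbed instance still satisfies every
caregiver range.  Both labels are re-checked internally before the
stream is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np

from .cdea import (ABNORMAL, NORMAL, ON, OFF, BehaviorInstance, MainSensor,
                   SensorEvent, SensorMap, SubSensor, parse_clock)
from .context_validator import CaregiverContext, FrequencyState, check_ranges

logger = logging.getLogger(__name__)

#: Simulation epoch: day 0 of every generated routine.
EPOCH = date(2024, 1, 1)

ANOMALY_KINDS = ("duration_shift", "start_time_shift", "frequency_shift",
                 "missing_activity")


class GenerationError(ValueError):
    pass


class AnomalySpecError(ValueError):
    pass


@dataclass(frozen=True)
class ActivitySpec:
    """Routine envelope for one ADL: where, with what, and when."""

    activity: str
    location: str
    object: str
    main_sensor_id: str
    start_time_window: tuple[time, time]
    duration_window: tuple[int, int]                 # minutes, inclusive
    daily_frequency_window: tuple[int, int] = (1, 1)
    sub_sensors: tuple[tuple[str, str], ...] = ()    # (SS id, sub-activity)
    sensor_type: str = "Binary"

    def __post_init__(self) -> None:
        if self.duration_window[0] <= 0:
            raise GenerationError(
                f"{self.activity}: duration lower bound must be positive")
        if self.duration_window[0] > self.duration_window[1]:
            raise GenerationError(f"{self.activity}: empty duration window")
        if self.daily_frequency_window[0] < 0:
            raise GenerationError(f"{self.activity}: negative frequency")
        if self.sub_sensors and self.duration_window[0] < 2 * len(self.sub_sensors) + 1:
            raise GenerationError(
                f"{self.activity}: duration window too short to sequence "
                f"{len(self.sub_sensors)} sub-activities")

    def start_minutes(self) -> tuple[int, int]:
        lo, hi = self.start_time_window
        return lo.hour * 60 + lo.minute, hi.hour * 60 + hi.minute


@dataclass(frozen=True)
class RoutineProfile:
    activities: tuple[ActivitySpec, ...]
    days: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise GenerationError("days must be >= 1")
        names = [a.activity for a in self.activities]
        if len(set(names)) != len(names):
            raise GenerationError("activity names must be distinct")

    def spec(self, activity: str) -> ActivitySpec:
        for a in self.activities:
            if a.activity == activity:
                return a
        raise KeyError(activity)

    def sensor_map(self) -> SensorMap:
        mains, subs = [], []
        for a in self.activities:
            mains.append(MainSensor(a.main_sensor_id, a.location, a.object,
                                    a.activity, a.sensor_type))
            for ss_id, sub_name in a.sub_sensors:
                subs.append(SubSensor(ss_id, sub_name, a.main_sensor_id))
        return SensorMap(mains, subs)


@dataclass
class Episode:
    """One scheduled occurrence of an activity (ground truth unit)."""

    activity: str
    day: int
    start: datetime
    duration: int
    perturbed: bool = False
    spec_index: Optional[int] = None   # which AnomalySpec produced it

    @property
    def end(self) -> datetime:
        return self.start + timedelta(minutes=self.duration)

    def key(self) -> tuple:
        return (self.activity, self.start)


@dataclass
class SimulatedStream:
    profile: RoutineProfile
    episodes: list[Episode]
    events: list[SensorEvent]
    sensor_map: SensorMap

    @property
    def labels(self) -> list[str]:
        return [ABNORMAL if e.perturbed else NORMAL for e in self.episodes]


def _day_dt(day: int, minute: int) -> datetime:
    return (datetime.combine(EPOCH, time(0, 0))
            + timedelta(days=day, minutes=minute))


def _draw_disjoint_starts(rng, lo: int, hi: int, durations: Sequence[int],
                          activity: str, day: int) -> list[int]:
    """Seeded disjoint occurrence starts inside [lo, hi] (minute grid)."""
    for _ in range(500):
        starts = sorted(int(rng.integers(lo, hi + 1))
                        for _ in durations)
        intervals = sorted((s, s + d) for s, d in zip(starts, durations))
        if all(b0 < a1 for (_, b0), (a1, _) in zip(intervals, intervals[1:])):
            return [a for a, _ in intervals]
    raise GenerationError(
        f"cannot schedule {len(durations)} non-overlapping occurrences of "
        f"{activity} on day {day}")


def schedule_routine(profile: RoutineProfile) -> list[Episode]:
    """Draw the full multi-day episode schedule from the profile windows."""
    rng = np.random.default_rng(profile.seed)
    episodes: list[Episode] = []
    for day in range(profile.days):
        for spec in profile.activities:
            f_lo, f_hi = spec.daily_frequency_window
            freq = int(rng.integers(f_lo, f_hi + 1))
            if freq == 0:
                continue
            d_lo, d_hi = spec.duration_window
            durations = [int(rng.integers(d_lo, d_hi + 1)) for _ in range(freq)]
            s_lo, s_hi = spec.start_minutes()
            if freq == 1:
                starts = [int(rng.integers(s_lo, s_hi + 1))]
            else:
                starts = _draw_disjoint_starts(rng, s_lo, s_hi, durations,
                                               spec.activity, day)
            for s, d in zip(starts, durations):
                episodes.append(Episode(spec.activity, day, _day_dt(day, s), d))
    episodes.sort(key=lambda e: (e.start, e.activity))
    return episodes


def render_events(episodes: Sequence[Episode],
                  profile: RoutineProfile) -> list[SensorEvent]:
    """Turn the episode schedule into the binary event stream.

    Per episode: main ON at start, each sub-activity as an ON/OFF pair in
    its fixed profile order (sequence matters: it is part of the behavior
    signature), then main OFF.  Same-sensor overlapping activations are a
    generation error naming the activity and day.
    """
    by_sensor: dict[str, list[Episode]] = {}
    events: list[tuple[datetime, int, SensorEvent]] = []
    order = 0
    for ep in episodes:
        spec = profile.spec(ep.activity)
        by_sensor.setdefault(spec.main_sensor_id, []).append(ep)
        events.append((ep.start, order, SensorEvent(spec.main_sensor_id, ON, ep.start)))
        order += 1
        t = ep.start
        for k, (ss_id, _) in enumerate(spec.sub_sensors):
            on_t = ep.start + timedelta(minutes=1 + 2 * k)
            off_t = on_t + timedelta(minutes=1)
            if off_t >= ep.end:
                break   # shrunken episode: drop sub-activities that no longer fit
            events.append((on_t, order, SensorEvent(ss_id, ON, on_t)))
            order += 1
            events.append((off_t, order, SensorEvent(ss_id, OFF, off_t)))
            order += 1
        events.append((ep.end, order, SensorEvent(spec.main_sensor_id, OFF, ep.end)))
        order += 1
    for sid, eps in by_sensor.items():
        eps = sorted(eps, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise GenerationError(
                    f"sensor {sid} ({b.activity}) activations overlap on day "
                    f"{b.day}: {a.start:%H:%M}-{a.end:%H:%M} vs {b.start:%H:%M}")
    events.sort(key=lambda rec: (rec[0], rec[1]))
    return [ev for _, _, ev in events]


def generate_routine(profile: RoutineProfile) -> SimulatedStream:
    """Generate the all-Normal multi-day event stream for a routine profile.

    Deterministic: identical profiles (including seed) yield identical
    streams.
    """
    episodes = schedule_routine(profile)
    events = render_events(episodes, profile)
    return SimulatedStream(profile, episodes, events, profile.sensor_map())


# ---------------------------------------------------------------------------
# Anomaly injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnomalySpec:
    """One requested behavior anomaly.

    ``magnitude`` is a signed minute delta for duration/start shifts and
    an occurrence count for frequency shifts; it is ignored for missing
    activities.  ``contextually_normal``, when set (and a caregiver
    context is supplied), declares the expected contextual ground truth
    and is verified before the perturbed stream is returned.  ``day``
    and ``occurrence`` pin the target; left unset they are drawn with
    the injection seed.
    """

    kind: str
    activity: str
    magnitude: int = 0
    contextually_normal: Optional[bool] = None
    day: Optional[int] = None
    occurrence: Optional[int] = None
    at: Optional[datetime] = None   # pin the exact scheduled start
    start_window: Optional[tuple[time, time]] = None  # for frequency_shift extras

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise AnomalySpecError(f"unknown anomaly kind {self.kind!r}")


@dataclass
class PerturbedStream:
    profile: RoutineProfile
    episodes: list[Episode]                  # day-ordered, incl. unperturbed
    events: list[SensorEvent]
    sensor_map: SensorMap
    labels: list[str]                        # per episode: Normal | Abnormal
    contextual_truth: list[Optional[bool]]   # per episode; None without context
    missing: list[dict] = field(default_factory=list)


def _routine_deviation(ep: Episode, spec: ActivitySpec,
                       day_count: int) -> bool:
    """Does the episode fall outside its activity's routine envelope?"""
    s_lo, s_hi = spec.start_minutes()
    minute = ep.start.hour * 60 + ep.start.minute
    d_lo, d_hi = spec.duration_window
    return (not s_lo <= minute <= s_hi
            or not d_lo <= ep.duration <= d_hi
            or day_count > spec.daily_frequency_window[1])


def evaluate_contextual_truth(episodes: Sequence[Episode],
                              profile: RoutineProfile,
                              context: CaregiverContext,
                              ) -> list[bool]:
    """Contextual ground truth per episode, day-ordered.

    Mirrors the validator's semantics: running per-day frequency counts
    over *all* episodes, increment before check, absent ranges pass,
    activities without any context entry cannot be contextually normal.
    """
    ordered = sorted(range(len(episodes)), key=lambda i: episodes[i].start)
    freq = FrequencyState()
    truth = [False] * len(episodes)
    for i in ordered:
        ep = episodes[i]
        inst = BehaviorInstance(
            start_time=ep.start, time_bin="", object="", location="",
            sub_activities=(), activity=ep.activity,
            duration_minutes=ep.duration, class_label=ABNORMAL)
        count = freq.observe(inst)
        if ep.activity in context:
            truth[i] = not check_ranges(inst, context[ep.activity], count)
        else:
            truth[i] = False
    return truth


def inject_anomalies(stream: SimulatedStream,
                     specs: Sequence[AnomalySpec],
                     context: CaregiverContext | None = None,
                     seed: int = 0) -> PerturbedStream:
    """Apply the requested anomalies and return the re-rendered stream.

    Every perturbed episode is verified to deviate from its routine
    envelope (it must be classifiable as Abnormal), and -- when a
    caregiver context is given and the spec declares an expectation --
    its contextual ground truth is re-derived and checked against the
    declaration.  An empty request returns the stream unchanged.
    """
    profile = stream.profile
    episodes = [replace(e) for e in stream.episodes]
    missing: list[dict] = []
    if specs:
        rng = np.random.default_rng(seed)
        known = {a.activity for a in profile.activities}
        for s_i, spec in enumerate(specs):
            if spec.activity not in known:
                raise AnomalySpecError(
                    f"anomaly references unknown activity {spec.activity!r}")
            if spec.kind == "missing_activity":
                _apply_missing(episodes, profile, spec, s_i, rng, missing,
                               context)
            elif spec.kind == "frequency_shift":
                _apply_frequency(episodes, profile, spec, s_i, rng)
            else:
                _apply_shift(episodes, profile, spec, s_i, rng)
        episodes.sort(key=lambda e: (e.start, e.activity))
        _verify_deviation(episodes, profile)
    events = render_events(episodes, profile)
    labels = [ABNORMAL if e.perturbed else NORMAL for e in episodes]
    truth: list[Optional[bool]] = [None] * len(episodes)
    if context is not None:
        truth = list(evaluate_contextual_truth(episodes, profile, context))
        by_spec: dict[int, list[int]] = {}
        for i, ep in enumerate(episodes):
            if ep.spec_index is not None:
                by_spec.setdefault(ep.spec_index, []).append(i)
        for s_i, spec in enumerate(specs):
            if spec.contextually_normal is None:
                continue
            for i in by_spec.get(s_i, []):
                if truth[i] != spec.contextually_normal:
                    raise AnomalySpecError(
                        f"spec {s_i} ({spec.kind} {spec.activity}): declared "
                        f"contextually_normal={spec.contextually_normal} but "
                        f"range evaluation says {truth[i]} for episode at "
                        f"{episodes[i].start}")
    return PerturbedStream(profile, episodes, events, stream.sensor_map,
                           labels, truth, missing)


def _pick_target(episodes, spec, rng) -> int:
    if spec.at is not None:
        for i, e in enumerate(episodes):
            if (e.activity == spec.activity and e.start == spec.at
                    and not e.perturbed):
                return i
        raise AnomalySpecError(
            f"no unperturbed {spec.activity} occurrence scheduled at {spec.at}")
    candidates = [i for i, e in enumerate(episodes)
                  if e.activity == spec.activity and not e.perturbed
                  and (spec.day is None or e.day == spec.day)]
    if not candidates:
        raise AnomalySpecError(
            f"no unperturbed {spec.activity} occurrence available"
            + (f" on day {spec.day}" if spec.day is not None else ""))
    if spec.occurrence is not None:
        day_cands = sorted(candidates, key=lambda i: episodes[i].start)
        if spec.occurrence >= len(day_cands):
            raise AnomalySpecError(
                f"occurrence {spec.occurrence} out of range for "
                f"{spec.activity}")
        return day_cands[spec.occurrence]
    return candidates[int(rng.integers(len(candidates)))]


def _apply_shift(episodes, profile, spec, s_i, rng) -> None:
    i = _pick_target(episodes, spec, rng)
    ep = episodes[i]
    if spec.kind == "duration_shift":
        new_dur = ep.duration + spec.magnitude
        if new_dur <= 0:
            raise AnomalySpecError(
                f"duration shift {spec.magnitude} on {ep.duration} min "
                f"{spec.activity} leaves no activity")
        episodes[i] = replace(ep, duration=new_dur, perturbed=True,
                              spec_index=s_i)
    else:  # start_time_shift
        episodes[i] = replace(
            ep, start=ep.start + timedelta(minutes=spec.magnitude),
            perturbed=True, spec_index=s_i)


def _apply_frequency(episodes, profile, spec, s_i, rng) -> None:
    if spec.magnitude <= 0:
        raise AnomalySpecError("frequency_shift needs a positive magnitude")
    aspec = profile.spec(spec.activity)
    day = spec.day if spec.day is not None else int(
        rng.integers(profile.days))
    window = spec.start_window or aspec.start_time_window
    lo = window[0].hour * 60 + window[0].minute
    hi = window[1].hour * 60 + window[1].minute
    existing = [(e.start, e.end) for e in episodes
                if e.activity == spec.activity and e.day == day]
    for _ in range(spec.magnitude):
        d_lo, d_hi = aspec.duration_window
        dur = int(rng.integers(d_lo, d_hi + 1))
        for _attempt in range(500):
            start = _day_dt(day, int(rng.integers(lo, hi + 1)))
            end = start + timedelta(minutes=dur)
            if all(end <= a or start >= b for a, b in existing):
                break
        else:
            raise AnomalySpecError(
                f"cannot place extra {spec.activity} occurrence on day {day}")
        existing.append((start, end))
        episodes.append(Episode(spec.activity, day, start, dur,
                                perturbed=True, spec_index=s_i))


def _apply_missing(episodes, profile, spec, s_i, rng, missing, context) -> None:
    days_with = sorted({e.day for e in episodes
                        if e.activity == spec.activity and not e.perturbed})
    if spec.day is not None:
        if spec.day not in days_with:
            raise AnomalySpecError(
                f"no {spec.activity} occurrences on day {spec.day}")
        day = spec.day
    elif days_with:
        day = days_with[int(rng.integers(len(days_with)))]
    else:
        raise AnomalySpecError(f"no {spec.activity} occurrences to remove")
    episodes[:] = [e for e in episodes
                   if not (e.activity == spec.activity and e.day == day)]
    ctx_ok: Optional[bool] = None
    if context is not None and spec.activity in context:
        f_rng = context[spec.activity].frequency_range
        ctx_ok = f_rng is None or f_rng[0] <= 0
    missing.append({"activity": spec.activity, "day": day,
                    "contextually_normal": ctx_ok, "spec_index": s_i})


def _verify_deviation(episodes, profile) -> None:
    day_counts: dict[tuple[str, int], int] = {}
    for e in episodes:
        day_counts[(e.activity, e.day)] = day_counts.get(
            (e.activity, e.day), 0) + 1
    for e in episodes:
        if e.perturbed and not _routine_deviation(
                e, profile.spec(e.activity),
                day_counts[(e.activity, e.day)]):
            raise AnomalySpecError(
                f"perturbed {e.activity} at {e.start} still lies inside the "
                "routine envelope; it cannot be an Abnormal instance")


# ---------------------------------------------------------------------------
# Default profile: ten ADLs in a four-room home
# ---------------------------------------------------------------------------

def default_profile(days: int = 14, seed: int = 7) -> RoutineProfile:
    """Ten-activity single-resident routine.

    Rooms: Bedroom, Bathroom, Kitchen, Living Room (plus the main door).
    Windows are chosen to be commensurate with the default hour time
    bins and 15-minute duration bins, so routine behavior is stable
    under itemization while injected anomalies land in distinct bins.
    """
    hm = parse_clock
    acts = (
        ActivitySpec("Sleeping", "Bedroom", "Bed", "SA-SLEEP",
                     (hm("23:05"), hm("23:25")), (480, 490)),
        ActivitySpec("Toileting", "Bathroom", "Toilet", "SA-TOILET",
                     (hm("08:05"), hm("21:40")), (5, 9), (4, 6),
                     (("SS-TOILET-BASIN", "Wash Basin"),
                      ("SS-TOILET-FLUSH", "Flush"))),
        ActivitySpec("Showering", "Bathroom", "Shower", "SA-SHOWER",
                     (hm("07:30"), hm("07:45")), (10, 14)),
        ActivitySpec("Breakfast", "Kitchen", "Toaster", "SA-BREAKFAST",
                     (hm("09:30"), hm("09:40")), (16, 29), (1, 1),
                     (("SS-BRK-FRIDGE", "Fridge"),
                      ("SS-BRK-CABINET", "Cabinet"),
                      ("SS-BRK-TOASTER", "Toaster"))),
        ActivitySpec("Lunch", "Kitchen", "Stove", "SA-LUNCH",
                     (hm("13:30"), hm("13:50")), (31, 44), (1, 1),
                     (("SS-LUN-FRIDGE", "Fridge"),
                      ("SS-LUN-CABINET", "Cabinet"),
                      ("SS-LUN-COOKTOP", "Cooktop"))),
        ActivitySpec("Dinner", "Kitchen", "Microwave", "SA-DINNER",
                     (hm("19:00"), hm("19:20")), (31, 44), (1, 1),
                     (("SS-DIN-FRIDGE", "Fridge"),
                      ("SS-DIN-CUPBOARD", "Cupboard"),
                      ("SS-DIN-MICROWAVE", "Microwave"))),
        ActivitySpec("Snack", "Kitchen", "Fridge", "SA-SNACK",
                     (hm("17:00"), hm("17:15")), (5, 10)),
        ActivitySpec("TV", "Living Room", "Sofa Chair", "SA-TV",
                     (hm("16:30"), hm("16:45")), (46, 59)),
        ActivitySpec("Grooming", "Bathroom", "Cabinet", "SA-GROOM",
                     (hm("08:30"), hm("08:40")), (5, 12)),
        ActivitySpec("Leaving", "", "Door", "SA-DOOR",
                     (hm("10:35"), hm("10:50")), (31, 44)),
    )
    return RoutineProfile(acts, days=days, seed=seed)
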