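"""Contextual data extraction: raw ON/OFF sensor events to behavior tuples.

A smart home instrumented with binary sensors emits a stream of
``(sensor_id, ON|OFF, timestamp)`` readings.  Sensors are of two kinds:
*main-activity* sensors (``SA``), each tied to one household object, one
location and one activity of daily living (ADL), and *sub-activity*
sensors (``SS``), each tied to a parent main sensor.  The extraction
procedure implemented here is a stateful sweep over the time-sorted
stream: a main-sensor ON opens a behavior instance, sub-sensor ONs
observed while the parent is open append sub-activities in order, and
the main-sensor OFF closes the instance and fixes its duration.

The resulting :class:`BehaviorInstance` carries the activity's start
time, a discretized time bin, the object used, the location, the ordered
sub-activities, the activity name, the duration in whole minutes and a
wellness class label (``Normal`` / ``Abnormal``, or ``UNKNOWN`` for test
instances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import yaml

logger = logging.getLogger(__name__)

ON = "ON"
OFF = "OFF"

NORMAL = "Normal"
ABNORMAL = "Abnormal"
UNKNOWN = "UNKNOWN"

#: Sentinel duration for an instance whose main-sensor OFF has not been seen.
UNDETERMINED = None


class CdeaError(ValueError):
    """Raised for malformed streams or unknown sensors."""


def parse_clock(text: str) -> time:
    """Parse a 24 h ``HH:MM`` clock string."""
    hh, mm = text.split(":")
    return time(int(hh), int(mm))


def format_clock(t: time) -> str:
    return f"{t.hour:02d}:{t.minute:02d}"


@dataclass(frozen=True)
class SensorEvent:
    """One binary reading from one sensor, at minute resolution."""

    sensor_id: str
    state: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if self.state not in (ON, OFF):
            raise CdeaError(f"state must be ON or OFF, got {self.state!r}")


@dataclass(frozen=True)
class MainSensor:
    sensor_id: str
    location: str
    object: str
    activity: str
    sensor_type: str = "Binary"


@dataclass(frozen=True)
class SubSensor:
    sensor_id: str
    sub_activity: str
    parent_id: str
    sensor_type: str = "Binary"


class SensorMap:
    """Installation map: which sensor means which object/location/activity.

    The analysis side holds this declaratively -- sensor-to-activity
    inference is out of scope; the mapping *is* the recognition step.
    """

    def __init__(self, main_sensors: Iterable[MainSensor],
                 sub_sensors: Iterable[SubSensor] = ()) -> None:
        self.main: dict[str, MainSensor] = {}
        self.sub: dict[str, SubSensor] = {}
        for s in main_sensors:
            if s.sensor_id in self.main:
                raise CdeaError(f"duplicate main sensor id {s.sensor_id!r}")
            self.main[s.sensor_id] = s
        for s in sub_sensors:
            if s.sensor_id in self.sub or s.sensor_id in self.main:
                raise CdeaError(f"sensor id {s.sensor_id!r} not unique")
            if s.parent_id not in self.main:
                raise CdeaError(
                    f"sub sensor {s.sensor_id!r} references unknown parent "
                    f"{s.parent_id!r}")
            self.sub[s.sensor_id] = s

    def __contains__(self, sensor_id: str) -> bool:
        return sensor_id in self.main or sensor_id in self.sub

    def to_dict(self) -> dict:
        return {
            "main_sensors": [vars(s) for s in self.main.values()],
            "sub_sensors": [vars(s) for s in self.sub.values()],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SensorMap":
        return cls(
            (MainSensor(**m) for m in d.get("main_sensors", [])),
            (SubSensor(**s) for s in d.get("sub_sensors", [])),
        )

    @classmethod
    def from_file(cls, path) -> "SensorMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class TimeDiscretization:
    """Partition of the 24 h clock into equal bins anchored at midnight."""

    bin_width_minutes: int = 60

    def __post_init__(self) -> None:
        if self.bin_width_minutes <= 0 or 1440 % self.bin_width_minutes:
            raise CdeaError(
                "bin width must be a positive divisor of 1440 minutes, got "
                f"{self.bin_width_minutes}")

    @property
    def n_bins(self) -> int:
        return 1440 // self.bin_width_minutes

    def bin_label(self, t: time) -> str:
        minute = t.hour * 60 + t.minute
        lo = (minute // self.bin_width_minutes) * self.bin_width_minutes
        hi = lo + self.bin_width_minutes
        fmt = lambda m: f"{(m // 60) % 24:02d}:{m % 60:02d}"
        return f"[{fmt(lo)},{fmt(hi)})"


def discretize_time(clock_time: time | datetime,
                    scheme: TimeDiscretization) -> str:
    """Map a clock time onto its discretized time bin label (total map)."""
    if isinstance(clock_time, datetime):
        clock_time = clock_time.time()
    return scheme.bin_label(clock_time)


def compute_duration(on_time: datetime, off_time: datetime) -> int:
    """Activity duration ``|end - start|`` in whole minutes.

    Calendar-aware: an activity spanning midnight (ON 23:30, OFF 07:15
    next day) has duration 465.  An OFF earlier than its ON is a stream
    defect, not a duration.
    """
    if off_time < on_time:
        raise CdeaError(
            f"OFF at {off_time} precedes ON at {on_time}")
    return int((off_time - on_time).total_seconds() // 60)


@dataclass(frozen=True)
class BehaviorInstance:
    """One contextually comprehensive behavior tuple.

    ``duration_minutes`` is :data:`UNDETERMINED` (``None``) exactly while
    the main sensor's OFF has not been observed.  ``class_label`` is
    ``UNKNOWN`` only for test instances awaiting classification.
    """

    start_time: datetime
    time_bin: str
    object: str
    location: str
    sub_activities: tuple[str, ...]
    activity: str
    duration_minutes: Optional[int]
    class_label: str = UNKNOWN

    @property
    def day(self):
        return self.start_time.date()

    def with_label(self, label: str) -> "BehaviorInstance":
        return replace(self, class_label=label)


@dataclass
class _OpenActivity:
    sensor: MainSensor
    start: datetime
    subs: list[str] = field(default_factory=list)


@dataclass
class OpenState:
    """Open main activities keyed by SA sensor id, plus skipped-event log."""

    open: dict[str, _OpenActivity] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def _warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)


def process_event(event: SensorEvent, smap: SensorMap,
                  state: OpenState,
                  scheme: TimeDiscretization | None = None,
                  ) -> Optional[BehaviorInstance]:
    """Advance the extraction state by one event.

    Returns a completed :class:`BehaviorInstance` when the event is a
    main-sensor OFF closing an open activity, else ``None``.  Sub-sensor
    events are only recognized while their parent main sensor is active;
    otherwise they are logged and skipped.  Unknown sensors are an error.
    """
    scheme = scheme or TimeDiscretization()
    sid = event.sensor_id
    if sid in smap.main:
        sensor = smap.main[sid]
        if event.state == ON:
            if sid in state.open:
                state._warn(
                    f"main sensor {sid} ON at {event.timestamp} while already "
                    "open; previous activation discarded")
            state.open[sid] = _OpenActivity(sensor, event.timestamp)
            return None
        # main OFF
        oa = state.open.pop(sid, None)
        if oa is None:
            state._warn(
                f"main sensor {sid} OFF at {event.timestamp} with no "
                "matching ON; skipped")
            return None
        return BehaviorInstance(
            start_time=oa.start,
            time_bin=discretize_time(oa.start, scheme),
            object=oa.sensor.object,
            location=oa.sensor.location,
            sub_activities=tuple(oa.subs),
            activity=oa.sensor.activity,
            duration_minutes=compute_duration(oa.start, event.timestamp),
            class_label=UNKNOWN,
        )
    if sid in smap.sub:
        sub = smap.sub[sid]
        if event.state == ON:
            oa = state.open.get(sub.parent_id)
            if oa is None:
                state._warn(
                    f"sub sensor {sid} ({sub.sub_activity}) at "
                    f"{event.timestamp} with no active parent "
                    f"{sub.parent_id}; skipped")
            elif sub.sub_activity not in oa.subs:
                # repeats of the same sub-activity collapse to one mention
                oa.subs.append(sub.sub_activity)
        return None
    raise CdeaError(f"unknown sensor id {sid!r} at {event.timestamp}")


def extract_instances(stream: Sequence[SensorEvent], smap: SensorMap,
                      scheme: TimeDiscretization | None = None,
                      state: OpenState | None = None,
                      ) -> list[BehaviorInstance]:
    """Run the full extraction sweep over a time-sorted event stream.

    Instances are returned ordered by start time.  Activities still open
    when the stream ends are emitted with UNDETERMINED duration (they are
    excluded from mining downstream, as they cannot form complete items).
    """
    scheme = scheme or TimeDiscretization()
    state = state or OpenState()
    last_ts = None
    out: list[BehaviorInstance] = []
    for ev in stream:
        if last_ts is not None and ev.timestamp < last_ts:
            raise CdeaError(
                f"stream not time-sorted at {ev.sensor_id} {ev.timestamp}")
        last_ts = ev.timestamp
        inst = process_event(ev, smap, state, scheme)
        if inst is not None:
            out.append(inst)
    for sid, oa in state.open.items():
        out.append(BehaviorInstance(
            start_time=oa.start,
            time_bin=discretize_time(oa.start, scheme),
            object=oa.sensor.object,
            location=oa.sensor.location,
            sub_activities=tuple(oa.subs),
            activity=oa.sensor.activity,
            duration_minutes=UNDETERMINED,
            class_label=UNKNOWN,
        ))
    out.sort(key=lambda i: i.start_time)
    return out
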