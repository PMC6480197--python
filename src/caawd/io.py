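"""Readers and writers for the tabular artifacts and the interchange dialect.

Event streams are CSV with columns ``timestamp`` (ISO 8601 local, minute
resolution), ``sensor_id``, ``state``.  Behavior instances are CSV with
one column per tuple field.  For interoperability with the widely used
ADL annotation layout, sensor activations can also be written and read
as tab-separated interval files (``Start time / End time / Location /
Type / Place``) with a companion activity-label file (``Start time /
End time / Activity``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import pandas as pd

from .cdea import (ON, OFF, BehaviorInstance, SensorEvent, SensorMap,
                   TimeDiscretization, discretize_time)

TS_FMT = "%Y-%m-%d %H:%M"
TS_FMT_SEC = "%Y-%m-%d %H:%M:%S"


class IOFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Event stream CSV
# ---------------------------------------------------------------------------

def write_events_csv(events: Sequence[SensorEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "sensor_id", "state"])
        for ev in events:
            w.writerow([ev.timestamp.strftime(TS_FMT), ev.sensor_id, ev.state])


def read_events_csv(path) -> list[SensorEvent]:
    out = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                ts = datetime.strptime(row["timestamp"], TS_FMT)
            except ValueError as exc:
                raise IOFormatError(f"{path}:{i}: bad timestamp "
                                    f"{row['timestamp']!r}") from exc
            out.append(SensorEvent(row["sensor_id"], row["state"], ts))
    return out


# ---------------------------------------------------------------------------
# Behavior instance CSV
# ---------------------------------------------------------------------------

INSTANCE_COLUMNS = ["start_time", "time_bin", "object", "location",
                    "sub_activities", "activity", "duration_minutes",
                    "class_label"]


def instances_to_frame(instances: Sequence[BehaviorInstance],
                       contextual_truth: Sequence[Optional[bool]] | None = None,
                       ) -> pd.DataFrame:
    rows = []
    for inst in instances:
        rows.append({
            "start_time": inst.start_time.strftime(TS_FMT),
            "time_bin": inst.time_bin,
            "object": inst.object,
            "location": inst.location,
            "sub_activities": "|".join(inst.sub_activities),
            "activity": inst.activity,
            "duration_minutes": ("" if inst.duration_minutes is None
                                 else inst.duration_minutes),
            "class_label": inst.class_label,
        })
    df = pd.DataFrame(rows, columns=INSTANCE_COLUMNS)
    if contextual_truth is not None:
        df["contextual_truth"] = ["" if t is None else str(t)
                                  for t in contextual_truth]
    return df


def write_instances_csv(instances, path, contextual_truth=None) -> None:
    instances_to_frame(instances, contextual_truth).to_csv(path, index=False)


def read_instances_csv(path,
                       scheme: TimeDiscretization | None = None,
                       ) -> list[BehaviorInstance]:
    scheme = scheme or TimeDiscretization()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        start = datetime.strptime(row["start_time"], TS_FMT)
        dur = row["duration_minutes"]
        out.append(BehaviorInstance(
            start_time=start,
            time_bin=row["time_bin"] or discretize_time(start, scheme),
            object=row["object"],
            location=row["location"],
            sub_activities=tuple(s for s in row["sub_activities"].split("|") if s),
            activity=row["activity"],
            duration_minutes=None if dur == "" else int(float(dur)),
            class_label=row["class_label"],
        ))
    return out


# ---------------------------------------------------------------------------
# Interval dialect (tab-separated sensor and label files)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledInterval:
    start: datetime
    end: datetime
    label: str


def _pair_events(events: Sequence[SensorEvent]) -> list[tuple[str, datetime, datetime]]:
    open_at: dict[str, datetime] = {}
    intervals = []
    for ev in events:
        if ev.state == ON:
            open_at[ev.sensor_id] = ev.timestamp
        else:
            start = open_at.pop(ev.sensor_id, None)
            if start is not None:
                intervals.append((ev.sensor_id, start, ev.timestamp))
    return intervals


def write_ordonez_dialect(events: Sequence[SensorEvent], smap: SensorMap,
                          path_sensors,
                          labeled: Sequence[LabeledInterval] = (),
                          path_labels=None) -> None:
    """Write paired sensor activations as tab-separated interval rows.

    ``Location`` is the instrumented object (or sub-activity), ``Type``
    the sensor technology, ``Place`` the room.  The dialect identifies
    sensors only by these descriptors, so a home with several sensors
    sharing (object, room) cannot be recovered losslessly.
    """
    with open(path_sensors, "w") as fh:
        fh.write("Start time\tEnd time\tLocation\tType\tPlace\n")
        for sid, start, end in sorted(_pair_events(events),
                                      key=lambda r: (r[1], r[0])):
            if sid in smap.main:
                s = smap.main[sid]
                loc, typ, place = s.object, s.sensor_type, s.location
            else:
                s = smap.sub[sid]
                parent = smap.main[s.parent_id]
                loc, typ, place = s.sub_activity, s.sensor_type, parent.location
            fh.write(f"{start.strftime(TS_FMT_SEC)}\t{end.strftime(TS_FMT_SEC)}"
                     f"\t{loc}\t{typ}\t{place}\n")
    if path_labels is not None:
        with open(path_labels, "w") as fh:
            fh.write("Start time\tEnd time\tActivity\n")
            for iv in labeled:
                fh.write(f"{iv.start.strftime(TS_FMT_SEC)}\t"
                         f"{iv.end.strftime(TS_FMT_SEC)}\t{iv.label}\n")


def read_ordonez_dialect(path_sensors, path_labels=None,
                         smap: SensorMap | None = None,
                         ) -> tuple[list[SensorEvent], list[LabeledInterval]]:
    """Read tab-separated interval files back into an event stream.

    Each sensor interval becomes an ON event at its start and an OFF at
    its end.  With a sensor map, rows are matched back to sensor ids by
    (object/sub-activity, room); otherwise synthetic ids are minted from
    the row descriptors.  Label intervals are returned as-is; assignment
    to instances (by maximal temporal overlap) is the caller's step.
    """
    by_desc: dict[tuple[str, str], str] = {}
    if smap is not None:
        for sid, s in smap.main.items():
            by_desc[(s.object, s.location)] = sid
        for sid, s in smap.sub.items():
            parent = smap.main[s.parent_id]
            by_desc[(s.sub_activity, parent.location)] = sid

    def parse_ts(text: str, lineno: int) -> datetime:
        for fmt in (TS_FMT_SEC, TS_FMT):
            try:
                return datetime.strptime(text, fmt)
            except ValueError:
                continue
        raise IOFormatError(f"{path_sensors}:{lineno}: bad timestamp {text!r}")

    events: list[SensorEvent] = []
    with open(path_sensors) as fh:
        header = fh.readline()
        if not header.lower().startswith("start time"):
            raise IOFormatError(f"{path_sensors}: missing header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise IOFormatError(
                    f"{path_sensors}:{lineno}: expected 5 tab-separated "
                    f"fields, got {len(parts)}")
            start = parse_ts(parts[0], lineno)
            end = parse_ts(parts[1], lineno)
            loc, _typ, place = parts[2], parts[3], parts[4]
            sid = by_desc.get((loc, place), f"{loc}@{place}")
            events.append(SensorEvent(sid, ON, start))
            events.append(SensorEvent(sid, OFF, end))
    events.sort(key=lambda ev: ev.timestamp)

    labels: list[LabeledInterval] = []
    if path_labels is not None:
        with open(path_labels) as fh:
            fh.readline()
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                labels.append(LabeledInterval(
                    parse_ts(parts[0], lineno), parse_ts(parts[1], lineno),
                    parts[2]))
    return events, labels


def assign_labels_by_overlap(instances: Sequence[BehaviorInstance],
                             labels: Sequence[LabeledInterval],
                             default: str = "Normal",
                             ) -> list[BehaviorInstance]:
    """Attach interval labels to instances by maximal temporal overlap."""
    out = []
    for inst in instances:
        if inst.duration_minutes is None:
            out.append(inst)
            continue
        from datetime import timedelta
        i_start = inst.start_time
        i_end = i_start + timedelta(minutes=inst.duration_minutes)
        best, best_overlap = default, 0.0
        for iv in labels:
            overlap = (min(i_end, iv.end) - max(i_start, iv.start)).total_seconds()
            if overlap > best_overlap:
                best, best_overlap = iv.label, overlap
        out.append(inst.with_label(best))
    return out
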