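"""Synthetic smart-home generator: schedules, events, anomaly injection."""

from collections import Counter, defaultdict
from datetime import time

import pytest

from caawd.cdea import ABNORMAL, NORMAL, ON, OFF
from caawd.context_validator import (ActivityContext, CaregiverContext,
                                     default_caregiver_context)
from caawd.synthetic_home import (ActivitySpec, AnomalySpec, AnomalySpecError,
                                  GenerationError, RoutineProfile,
                                  default_profile, generate_routine,
                                  inject_anomalies)
from caawd.benchmarks import labeled_instances

from oracles import brute_context_check


def point_profile(days=1, duration=30):
    """Degenerate profile: all windows collapsed to points."""
    spec = ActivitySpec("Nap", "Living Room", "Sofa", "SA-NAP",
                        (time(15, 0), time(15, 0)), (duration, duration))
    return RoutineProfile((spec,), days=days, seed=0)


class TestGenerateRoutine:
    def test_degenerate_windows_give_exact_schedule(self):
        """Point windows produce exactly one ON and one OFF with the point
        duration."""
        stream = generate_routine(point_profile())
        assert [(e.sensor_id, e.state) for e in stream.events] == \
            [("SA-NAP", ON), ("SA-NAP", OFF)]
        on, off = stream.events
        assert (off.timestamp - on.timestamp).total_seconds() == 30 * 60
        assert on.timestamp.time() == time(15, 0)

    def test_determinism_under_fixed_seed(self):
        """Identical profiles (seed included) yield identical streams."""
        a = generate_routine(default_profile(days=14, seed=7))
        b = generate_routine(default_profile(days=14, seed=7))
        assert a.events == b.events
        assert a.episodes == b.episodes
        c = generate_routine(default_profile(days=14, seed=8))
        assert c.events != a.events

    def test_starts_inside_declared_windows(self):
        """Exhaustive scan of the emitted stream: every main-sensor ON
        falls inside its activity's start window."""
        profile = default_profile(days=14, seed=3)
        stream = generate_routine(profile)
        by_sensor = {a.main_sensor_id: a for a in profile.activities}
        for ev in stream.events:
            if ev.sensor_id in by_sensor and ev.state == ON:
                spec = by_sensor[ev.sensor_id]
                lo, hi = spec.start_time_window
                assert lo <= ev.timestamp.time() <= hi

    def test_event_well_formedness(self):
        """Each ON has exactly one later OFF per sensor, and sub events
        occur only while their parent main sensor is ON."""
        stream = generate_routine(default_profile(days=7, seed=1))
        open_state = {}
        smap = stream.sensor_map
        for ev in stream.events:
            if ev.sensor_id in smap.main:
                if ev.state == ON:
                    assert ev.sensor_id not in open_state
                    open_state[ev.sensor_id] = ev.timestamp
                else:
                    assert ev.sensor_id in open_state
                    assert open_state.pop(ev.sensor_id) <= ev.timestamp
            else:
                parent = smap.sub[ev.sensor_id].parent_id
                assert parent in open_state
        assert not open_state

    def test_overlapping_same_sensor_is_an_error(self):
        spec = ActivitySpec("Nap", "Living Room", "Sofa", "SA-NAP",
                            (time(15, 0), time(15, 0)), (120, 120), (2, 2))
        with pytest.raises(GenerationError, match="Nap"):
            generate_routine(RoutineProfile((spec,), days=1, seed=0))

    def test_all_labels_normal(self):
        stream = generate_routine(default_profile(days=2, seed=0))
        assert set(stream.labels) == {NORMAL}


class TestInjectAnomalies:
    def test_empty_request_returns_stream_unchanged(self):
        stream = generate_routine(default_profile(days=3, seed=2))
        out = inject_anomalies(stream, [], seed=0)
        assert out.events == stream.events
        assert set(out.labels) == {NORMAL}

    def test_requested_counts_are_exact(self):
        stream = generate_routine(default_profile(days=14, seed=2))
        specs = [AnomalySpec("duration_shift", "Sleeping", magnitude=165,
                             day=d) for d in range(5)]
        out = inject_anomalies(stream, specs, seed=1)
        assert Counter(out.labels)[ABNORMAL] == 5

    def test_oversleep_within_bed_rest_is_contextually_normal(self):
        """+2 h on an 8 h baseline stays inside a 12 h bed-rest limit:
        the generator's flag agrees with direct range evaluation."""
        ctx = CaregiverContext({"Sleeping": ActivityContext(
            duration_range=(0, 12 * 60))})
        stream = generate_routine(default_profile(days=3, seed=4))
        spec = AnomalySpec("duration_shift", "Sleeping", magnitude=120,
                           contextually_normal=True, day=1)
        out = inject_anomalies(stream, [spec], context=ctx, seed=0)
        idx = [i for i, e in enumerate(out.episodes) if e.perturbed]
        assert len(idx) == 1
        assert out.contextual_truth[idx[0]] is True
        inst, truth = labeled_instances(out)
        finals = brute_context_check(
            [i.with_label(out.labels[j]) for j, i in enumerate(inst)], ctx)
        assert finals[idx[0]] == NORMAL

    def test_declared_flag_is_verified(self):
        """A declared contextually-normal anomaly that actually violates
        the caregiver range is rejected."""
        ctx = CaregiverContext({"Sleeping": ActivityContext(
            duration_range=(0, 9 * 60))})
        stream = generate_routine(default_profile(days=3, seed=4))
        spec = AnomalySpec("duration_shift", "Sleeping", magnitude=240,
                           contextually_normal=True, day=1)
        with pytest.raises(AnomalySpecError, match="declared"):
            inject_anomalies(stream, [spec], context=ctx, seed=0)

    def test_in_envelope_perturbation_rejected(self):
        """A magnitude too small to leave the routine envelope cannot be
        an anomaly."""
        stream = generate_routine(default_profile(days=2, seed=0))
        spec = AnomalySpec("duration_shift", "Sleeping", magnitude=0, day=0)
        with pytest.raises(AnomalySpecError, match="routine envelope"):
            inject_anomalies(stream, [spec], seed=0)

    def test_missing_activity_emits_no_events(self):
        stream = generate_routine(default_profile(days=3, seed=1))
        spec = AnomalySpec("missing_activity", "Leaving", day=1)
        out = inject_anomalies(stream, [spec], seed=0)
        door_days = {e.timestamp.day for e in out.events
                     if e.sensor_id == "SA-DOOR"}
        assert out.missing == [{"activity": "Leaving", "day": 1,
                                "contextually_normal": None, "spec_index": 0}]
        assert 2 not in door_days  # day index 1 = Jan 2 of the epoch

    def test_frequency_shift_adds_occurrences(self):
        stream = generate_routine(default_profile(days=2, seed=1))
        spec = AnomalySpec("frequency_shift", "Toileting", magnitude=3, day=0,
                           start_window=(time(1, 0), time(5, 0)))
        out = inject_anomalies(stream, [spec], seed=0)
        added = [e for e in out.episodes if e.perturbed]
        assert len(added) == 3
        assert all(e.activity == "Toileting" and e.day == 0 for e in added)
        assert all(time(1, 0) <= e.start.time() <= time(5, 0) for e in added)

    def test_unknown_activity_rejected(self):
        stream = generate_routine(default_profile(days=2, seed=1))
        with pytest.raises(AnomalySpecError, match="unknown activity"):
            inject_anomalies(stream,
                             [AnomalySpec("duration_shift", "Juggling",
                                          magnitude=60)], seed=0)

    def test_label_soundness_against_range_oracle(self):
        """Re-deriving every contextual flag with the independent oracle
        reproduces the generator's flags on 100% of instances."""
        ctx = default_caregiver_context()
        stream = generate_routine(default_profile(days=5, seed=6))
        specs = [AnomalySpec("duration_shift", "Showering", magnitude=120,
                             contextually_normal=False, day=d)
                 for d in range(5)]
        out = inject_anomalies(stream, specs, context=ctx, seed=0)
        insts, truth = labeled_instances(out)
        labeled = [i for i in insts]
        finals = brute_context_check(labeled, ctx)
        for i, (inst, flag) in enumerate(zip(insts, truth)):
            if inst.class_label == ABNORMAL:
                assert (finals[i] == NORMAL) == flag


class TestProfileValidation:
    def test_days_and_distinct_names(self):
        spec = point_profile().activities[0]
        with pytest.raises(GenerationError):
            RoutineProfile((spec,), days=0, seed=0)
        with pytest.raises(GenerationError, match="distinct"):
            RoutineProfile((spec, spec), days=1, seed=0)

    def test_duration_lower_bound_positive(self):
        with pytest.raises(GenerationError, match="positive"):
            ActivitySpec("X", "L", "O", "SA-X", (time(1, 0), time(2, 0)),
                         (0, 10))
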