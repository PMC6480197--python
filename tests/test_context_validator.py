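"""Caregiver-context validation: AND logic, frequency counting, alarms."""

import random
from datetime import datetime, time, timedelta

import pytest

from caawd.cdea import ABNORMAL, NORMAL, BehaviorInstance
from caawd.context_validator import (ActivityContext, AlarmRecord,
                                     CaregiverContext, ContextError,
                                     FrequencyState, batch_validate,
                                     check_ranges, default_caregiver_context,
                                     emit_alarm, validate)
from caawd.worked_examples import bed_rest_context, oversleep_test_instance

from oracles import brute_context_check


def make_instance(activity="Sleeping", day=1, hh=23, mm=0, duration=480,
                  label=ABNORMAL, location="Bedroom", obj="Bed"):
    start = datetime(2024, 1, day, hh, mm)
    return BehaviorInstance(start, "", obj, location, (), activity,
                            duration, label)


class TestValidate:
    def test_oversleep_excused_by_bed_rest_note(self):
        """11.5 h daytime sleep is inside the 12 h bed-rest limit; with no
        other range prescribed the abnormal call is corrected to Normal."""
        inst = oversleep_test_instance().with_label(ABNORMAL)
        final, violations, _ = validate(inst, bed_rest_context(),
                                        FrequencyState())
        assert final == NORMAL
        assert violations == []

    def test_nocturnal_sleep_start_violates_window(self):
        """Going to bed at 02:30 falls outside the caregiver's
        22:30-23:30 start window regardless of duration."""
        inst = make_instance(hh=2, mm=30, duration=480)
        final, violations, _ = validate(inst, default_caregiver_context(),
                                        FrequencyState())
        assert final == ABNORMAL
        assert any(v.attribute == "start_time" for v in violations)

    def test_ninth_toileting_violates_frequency(self):
        """A ninth daily toileting exceeds the 4-8 range even when its
        duration and start pass every other check."""
        ctx = default_caregiver_context()
        freq = FrequencyState()
        for _ in range(8):
            freq.observe(make_instance("Toileting", hh=10, duration=5))
        inst = make_instance("Toileting", hh=11, duration=5)
        final, violations, _ = validate(inst, ctx, freq)
        assert final == ABNORMAL
        assert [v.attribute for v in violations] == ["frequency"]
        assert violations[0].observed == 9

    def test_count_includes_current_instance(self):
        """The frequency check sees the instance being validated: the
        first toileting of a day already counts as 1."""
        inst = make_instance("Toileting", hh=10, duration=5)
        final, violations, _ = validate(inst, default_caregiver_context(),
                                        FrequencyState())
        assert final == ABNORMAL  # 1 below the 4-8 minimum
        assert violations[0].observed == 1

    def test_no_context_policy(self):
        inst = make_instance("Knitting")
        final, _, reason = validate(inst, default_caregiver_context(),
                                    FrequencyState())
        assert (final, reason) == (ABNORMAL, "no context defined")
        final, _, _ = validate(inst, default_caregiver_context(),
                               FrequencyState(), no_context_policy="normal")
        assert final == NORMAL

    def test_normal_input_rejected(self):
        with pytest.raises(ContextError):
            validate(make_instance(label=NORMAL), default_caregiver_context(),
                     FrequencyState())


class TestBatchValidate:
    def test_all_normal_passthrough(self):
        insts = [make_instance(label=NORMAL, day=d) for d in range(1, 4)]
        report = batch_validate(insts, default_caregiver_context())
        assert report.reclassified_count == 0
        assert report.final_labels == [NORMAL] * 3

    def test_unordered_input_is_an_error(self):
        insts = [make_instance(day=2), make_instance(day=1)]
        with pytest.raises(ContextError, match="ordered"):
            batch_validate(insts, default_caregiver_context())

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_range_check_oracle(self, seed):
        """Batch verdicts equal an independent literal re-derivation on
        random instances spanning several days and activities."""
        rng = random.Random(seed)
        ctx = default_caregiver_context()
        activities = ["Sleeping", "Toileting", "Breakfast", "Showering",
                      "Knitting"]
        insts = []
        t = datetime(2024, 2, 1, 0, 0)
        for _ in range(100):
            t += timedelta(minutes=rng.randint(10, 400))
            insts.append(BehaviorInstance(
                t, "", "", "", (), rng.choice(activities),
                rng.randint(0, 800),
                rng.choice([NORMAL, ABNORMAL])))
        report = batch_validate(insts, ctx)
        assert report.final_labels == brute_context_check(insts, ctx)

    def test_per_day_frequency_counts(self):
        """Final per-(activity, day) counts equal the instances observed,
        Normal-classified ones included."""
        insts = sorted(
            [make_instance("Toileting", day=1, hh=h, duration=5, label=NORMAL)
             for h in (8, 9)]
            + [make_instance("Toileting", day=1, hh=10, duration=5)]
            + [make_instance("Toileting", day=2, hh=8, duration=5)],
            key=lambda i: i.start_time)
        ctx = default_caregiver_context()
        report = batch_validate(insts, ctx)
        # day 1 third toileting: count 3, below the 4-8 minimum
        assert report.records[2].violations[0].observed == 3
        # day 2 restarts at 1
        assert report.records[3].violations[0].observed == 1


class TestMonotonicity:
    def test_widening_ranges_never_turns_normal_abnormal(self):
        """Widening any caregiver range can only excuse more instances."""
        rng = random.Random(1)
        insts = []
        t = datetime(2024, 3, 1, 0, 0)
        for _ in range(60):
            t += timedelta(minutes=rng.randint(30, 300))
            insts.append(BehaviorInstance(t, "", "", "", (), "Sleeping",
                                          rng.randint(100, 900), ABNORMAL))
        narrow = CaregiverContext({"Sleeping": ActivityContext(
            (1, 2), (400, 600), (time(20, 0), time(23, 0)))})
        wide = CaregiverContext({"Sleeping": ActivityContext(
            (0, 5), (300, 800), (time(18, 0), time(23, 59)))})
        before = batch_validate(insts, narrow).final_labels
        after = batch_validate(insts, wide).final_labels
        for b, a in zip(before, after):
            if b == NORMAL:
                assert a == NORMAL

    def test_absent_ranges_pass_vacuously(self):
        inst = make_instance("Toileting", hh=3, duration=500)
        actx = ActivityContext()  # caregiver prescribed nothing
        assert check_ranges(inst, actx, frequency_count=50) == []


class TestAlarms:
    def test_temporal_deviation_alarm(self):
        """A nocturnal sofa sleep deviating from the afternoon-nap routine
        produces an alarm naming the activity and the deviation."""
        inst = make_instance("Sleeping", hh=23, mm=40, duration=290,
                             location="Living Room", obj="Sofa")
        final, violations, _ = validate(
            inst, CaregiverContext({"Sleeping": ActivityContext(
                start_time_range=(time(15, 30), time(16, 45)))}),
            FrequencyState())
        assert final == ABNORMAL
        alarm = emit_alarm(inst, violations)
        assert "Sleeping" in alarm.description
        assert "Living Room" in alarm.description
        assert "start_time" in str(alarm.violated)

    def test_single_violation_lists_one_attribute(self):
        inst = make_instance("Sleeping", hh=23, mm=0, duration=900)
        ctx = default_caregiver_context()
        _, violations, _ = validate(inst, ctx, FrequencyState())
        # start and frequency may pass; duration must be the cited cause
        alarm = emit_alarm(inst, [v for v in violations
                                  if v.attribute == "duration"])
        assert len(alarm.violated) == 1
        assert alarm.violated[0]["attribute"] == "duration"

    def test_alarm_json_round_trip(self):
        inst = make_instance("Toileting", hh=3, duration=5)
        alarm = emit_alarm(inst, [])
        assert AlarmRecord.from_json(alarm.to_json()) == alarm

    def test_alarm_on_normal_instance_rejected(self):
        with pytest.raises(ContextError):
            emit_alarm(make_instance(label=NORMAL))


class TestContextFile:
    def test_yaml_round_trip(self, tmp_path):
        ctx = default_caregiver_context()
        path = tmp_path / "context.yaml"
        ctx.to_file(path)
        loaded = CaregiverContext.from_file(path)
        assert loaded.to_dict() == ctx.to_dict()

    def test_invalid_range_rejected(self):
        with pytest.raises(ContextError, match="min > max"):
            ActivityContext(frequency_range=(5, 2))
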