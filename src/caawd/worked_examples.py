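"""Small hand-built scenarios used in documentation, examples and tests.

These are desk-checkable fixtures: a single kitchen cooking episode
seen through its raw sensor events, and a night-sleeper routine with a
daytime-oversleep test case that the classifier should flag and the
caregiver context (bed rest recommended up to 12 h) should excuse.
"""

from __future__ import annotations

from datetime import datetime, timedelta

from .car_miner import ItemizationScheme
from .cdea import (ABNORMAL, NORMAL, ON, OFF, UNKNOWN, BehaviorInstance,
                   MainSensor, SensorEvent, SensorMap, SubSensor,
                   TimeDiscretization, discretize_time)
from .context_validator import ActivityContext, CaregiverContext


def kitchen_sensor_map() -> SensorMap:
    """Stove main sensor in the kitchen with cabinet and cooktop subs."""
    return SensorMap(
        [MainSensor("03", "Kitchen", "Stove", "Cook")],
        [SubSensor("SS-CABINET", "Cabinet", "03"),
         SubSensor("SS-COOKTOP", "Cooktop", "03")],
    )


def kitchen_cook_events(day: datetime | None = None) -> list[SensorEvent]:
    """A five-minute cooking episode, 11:30-11:35.

    The resident opens the cabinet while the stove sensor is active,
    then uses the cooktop; the completed behavior tuple is
    (11:30, Stove, Kitchen, [Cabinet, Cooktop], Cook, 5 min).
    """
    base = day or datetime(2024, 1, 1)
    t = lambda hh, mm: base.replace(hour=hh, minute=mm)
    return [
        SensorEvent("03", ON, t(11, 30)),
        SensorEvent("SS-CABINET", ON, t(11, 30)),
        SensorEvent("SS-CABINET", OFF, t(11, 31)),
        SensorEvent("SS-COOKTOP", ON, t(11, 31)),
        SensorEvent("SS-COOKTOP", OFF, t(11, 34)),
        SensorEvent("03", OFF, t(11, 35)),
    ]


def _sleep_instance(day: int, hh: int, mm: int, duration: int,
                    label: str, scheme: TimeDiscretization) -> BehaviorInstance:
    start = datetime(2024, 1, 1 + day, hh, mm)
    return BehaviorInstance(
        start_time=start,
        time_bin=discretize_time(start, scheme),
        object="Bed", location="Bedroom", sub_activities=(),
        activity="Sleeping", duration_minutes=duration, class_label=label)


def sleeping_routine_training(scheme: ItemizationScheme | None = None,
                              ) -> list[BehaviorInstance]:
    """Training set for the night-sleeper worked example.

    Fourteen nights of the learned routine -- to bed at 23:30 for
    7 h 45 m -- labeled Normal, plus four labeled deviations (daytime
    oversleeps around 9:30-9:45 lasting about 11.5 h) labeled Abnormal.
    The deviations are what lets the rule base carry Abnormal-consequent
    rules at all; a routine-only training set can only ever assert
    normality.
    """
    td = (scheme or ItemizationScheme()).time
    rows = [_sleep_instance(d, 23, 30, 465, NORMAL, td) for d in range(14)]
    rows += [
        _sleep_instance(14, 9, 30, 690, ABNORMAL, td),
        _sleep_instance(15, 9, 45, 695, ABNORMAL, td),
        _sleep_instance(16, 9, 35, 700, ABNORMAL, td),
        _sleep_instance(17, 9, 40, 692, ABNORMAL, td),
    ]
    return rows


def oversleep_test_instance(scheme: ItemizationScheme | None = None,
                            ) -> BehaviorInstance:
    """Test case: in bed at 9:30 in the morning for 11 h 30 m."""
    td = (scheme or ItemizationScheme()).time
    return _sleep_instance(20, 9, 30, 690, UNKNOWN, td)


def bed_rest_context() -> CaregiverContext:
    """Caregiver note for the oversleep example: bed rest recommended,
    any sleep up to 12 h is acceptable; no other range prescribed."""
    return CaregiverContext({
        "Sleeping": ActivityContext(duration_range=(0, 12 * 60)),
    })
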