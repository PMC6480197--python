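import random
from datetime import datetime, timedelta

import pytest

from caawd.car_miner import ItemizationScheme
from caawd.cdea import (ON, OFF, MainSensor, SensorEvent, SensorMap,
                        SubSensor, TimeDiscretization)


@pytest.fixture
def scheme():
    return ItemizationScheme(TimeDiscretization(60), 15)


@pytest.fixture
def two_room_map():
    """Two main sensors (kitchen stove, bedroom bed), stove has two subs."""
    return SensorMap(
        [MainSensor("SA1", "Kitchen", "Stove", "Cook"),
         MainSensor("SA2", "Bedroom", "Bed", "Sleeping")],
        [SubSensor("SS1", "Cabinet", "SA1"),
         SubSensor("SS2", "Cooktop", "SA1")],
    )


def random_event_stream(rng: random.Random, smap: SensorMap, n_episodes: int):
    """Well-formed random stream: disjoint per-sensor episodes with sub
    bursts strictly inside their parent's interval."""
    t = datetime(2024, 3, 1, 0, 0)
    events = []
    for _ in range(n_episodes):
        sid = rng.choice(list(smap.main))
        t += timedelta(minutes=rng.randint(1, 30))
        start = t
        dur = rng.randint(2, 40)
        events.append(SensorEvent(sid, ON, start))
        subs = [s for s in smap.sub.values() if s.parent_id == sid]
        offset = 1
        for sub in subs:
            if rng.random() < 0.6 and offset + 1 < dur:
                on_t = start + timedelta(minutes=offset)
                events.append(SensorEvent(sub.sensor_id, ON, on_t))
                events.append(SensorEvent(sub.sensor_id, OFF,
                                          on_t + timedelta(minutes=1)))
                offset += 2
        t = start + timedelta(minutes=dur)
        events.append(SensorEvent(sid, OFF, t))
    events.sort(key=lambda e: e.timestamp)
    return events


def random_itemized_dataset(rng: random.Random, n: int, n_attrs: int = 5,
                            n_values: int = 3, max_items: int = 8):
    """Random labeled transactions over a small attribute=value vocabulary."""
    data = []
    for _ in range(n):
        items = set()
        for a in range(rng.randint(1, min(n_attrs, max_items))):
            items.add((f"a{a}", f"v{rng.randint(0, n_values - 1)}"))
        label = rng.choice(["Normal", "Abnormal"])
        data.append((frozenset(items), label))
    return data
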