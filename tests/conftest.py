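from datetime import datetime, timedelta

import numpy as np
import pytest

from mobisense.events_io import SensorEvent, sensor_category


def make_event(ts, sensor_id="M001", value="ON", activity=None, location=None):
    """Event with category derived from the id prefix."""
    if isinstance(ts, (int, float)):
        ts = datetime(2024, 3, 4, 9, 0, 0) + timedelta(seconds=ts)
    return SensorEvent(timestamp=ts, sensor_id=sensor_id, value=value,
                       category=sensor_category(sensor_id),
                       location=location, activity=activity)


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)


@pytest.fixture
def random_events(rng):
    """1,000 motion/door events over a few days, timestamp-sorted."""
    base = datetime(2024, 3, 4)
    sensors = ["M001", "M002", "M003", "D001"]
    offsets = np.sort(rng.uniform(0, 3 * 86400, size=1000))
    events = []
    for off in offsets:
        sid = sensors[int(rng.integers(len(sensors)))]
        value = "OPEN" if sid.startswith("D") else "ON"
        events.append(make_event(base + timedelta(seconds=float(off)),
                                 sensor_id=sid, value=value))
    return events
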