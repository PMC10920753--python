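import datetime as dt

import pytest

from mmerisk import EventTable, GeneratorConfig, MortalityEvent, generate_events
from mmerisk.synthetic import GpdTailMagnitude


@pytest.fixture
def tiny_events() -> EventTable:
    """Three hand-built monthly records from one country (total 60 fish)."""
    return EventTable(
        [
            MortalityEvent("Testland", "siteA", dt.date(2015, 1, 1), "monthly", 10),
            MortalityEvent("Testland", "siteB", dt.date(2015, 1, 1), "monthly", 20),
            MortalityEvent("Testland", "siteA", dt.date(2015, 2, 1), "monthly", 30),
        ]
    )


@pytest.fixture
def events_csv(tmp_path):
    """A well-formed 3-row event CSV on disk."""
    path = tmp_path / "events.csv"
    path.write_text(
        "country,unit_id,period_start,resolution,fish_lost,latitude,longitude\n"
        "Testland,siteA,2015-01-01,monthly,10,60.1,5.2\n"
        "Testland,siteB,2015-01-01,monthly,20,,\n"
        "Testland,siteA,2015-02-01,monthly,30,60.3,5.4\n"
    )
    return path


@pytest.fixture(scope="session")
def heavy_tail_country() -> tuple[EventTable, GpdTailMagnitude]:
    """A decade-long synthetic country whose tail above 100k fish is exactly
    GPD(0.2, 50k), large enough for >= 500 POT exceedances at the top-10% rule."""
    magnitude = GpdTailMagnitude(
        body_scale=100_000.0, tail_shape=0.2, tail_scale=50_000.0, tail_fraction=0.10
    )
    config = GeneratorConfig(
        country="Synthia", start="2012-01", end="2021-12",
        base_rate=45.0, magnitude=magnitude, seed=2024,
    )
    return generate_events(config), magnitude
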