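from datetime import datetime, timedelta

import pytest

from smbgloop.titration import GlucoseReading, Regimen, ReviewWindow, make_window

WEEK_START = datetime(2021, 1, 4)  # a Monday


def reading(glucose, slot="prebreakfast", day=0, hour=None, pid="P001",
            assisted=False):
    if hour is None:
        hour = 8 if slot == "prebreakfast" else 18
    return GlucoseReading(participant_id=pid,
                          time=WEEK_START + timedelta(days=day, hours=hour),
                          slot=slot, glucose=glucose, assisted_event=assisted)


def week_window(prebreakfast=(), predinner=()):
    """Build a 7-day review window from per-slot glucose sequences
    (one reading per day per slot, in order)."""
    readings = [reading(g, "prebreakfast", day=i) for i, g in enumerate(prebreakfast)]
    readings += [reading(g, "predinner", day=i) for i, g in enumerate(predinner)]
    return make_window(readings, WEEK_START)


@pytest.fixture
def regimen():
    return Regimen(morning_dose=30, evening_dose=20, weight_kg=80.0)
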