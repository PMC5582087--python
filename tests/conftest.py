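import datetime as dt

import numpy as np
import pytest

from damsleep import ActivitySeries, LightSchedule, StimulusSchedule, default_profiles

START = dt.datetime(2016, 6, 1, 8, 0)  # lights-on, ZT0


def make_series(counts, bin_minutes=1, start=START, mask=None, fly_id="fly"):
    return ActivitySeries(
        fly_id=fly_id,
        counts=np.asarray(counts),
        bin_minutes=bin_minutes,
        start=start,
        schedule=LightSchedule(),
        mask=mask,
    )


@pytest.fixture
def profiles():
    return default_profiles()


@pytest.fixture
def stimulus():
    return StimulusSchedule()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
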