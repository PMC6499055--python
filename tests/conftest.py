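from datetime import date, datetime

import numpy as np
import pytest

from colonypulse.feature_bank import build_band_layout
from colonypulse.night_schedule import compute_night
from colonypulse.study import SITE_LAT, SITE_LON, SITE_UTC_OFFSET, train_call_models

T0 = datetime(2015, 7, 17, 6, 0, 0)  # arbitrary UTC clip timestamp for fixtures


@pytest.fixture(scope="session")
def fbank():
    return build_band_layout()


@pytest.fixture(scope="session")
def schedule_july():
    """Mid-July night at the Goat Island site (new-moon period)."""
    return compute_night(SITE_LAT, SITE_LON, date(2015, 7, 10), SITE_UTC_OFFSET)


@pytest.fixture(scope="session")
def call_models(fbank):
    """Aerial + ground classifiers trained once per session on synthetic clips."""
    return train_call_models(fbank, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
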