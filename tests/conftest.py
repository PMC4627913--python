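import numpy as np
import pandas as pd
import pytest

from transloc import tables
from transloc.telemetry import Track


@pytest.fixture(scope="session")
def study_records():
    """The 23-adult study cohort from the packaged tables."""
    return tables.load_study_records()


@pytest.fixture(scope="session")
def movement_df():
    return tables.load_movement_df()


def make_daily_track(xy, individual_id="t", start="2010-01-01 12:00"):
    """Build a standardized daily track from an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    ts = pd.Timestamp(start, tz="UTC") + pd.to_timedelta(np.arange(n), unit="D")
    df = pd.DataFrame(
        {
            "timestamp": ts,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "source": "GPS",
            "quality": np.nan,
            "day_index": np.arange(n),
        }
    )
    return Track(individual_id, df, release_time=ts[0])


@pytest.fixture
def daily_track_factory():
    return make_daily_track
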