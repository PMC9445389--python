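import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from locotrack.config import DaySchedule, GapModel, Priors, RoundSpec, SimConfig, default_rounds
from locotrack.kinematics import build_antenna_grid
from locotrack.rfid_io import BirdDayStream


@pytest.fixture(scope="session")
def grid():
    """The reference 5 x 6 antenna grid in a 1.8 x 2.6 m pen."""
    return build_antenna_grid(5, 6, 1.8, 2.6)


@pytest.fixture(scope="session")
def schedule():
    return DaySchedule()


@pytest.fixture(scope="session")
def small_sim_config():
    """Two short rounds of 8 birds, gap injection off (deterministic tests
    add their own exclusions)."""
    rounds = tuple(dataclasses.replace(r, n_birds=8) for r in default_rounds()[:2])
    return SimConfig(rounds=rounds, seed=11, gap_model=GapModel(rate_per_day=0.0))


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    from locotrack.synthetic import generate_dataset

    return generate_dataset(small_sim_config, Priors(), outdir=None)


def make_stream(times, antennas, segments=None, effective_seconds=57_600,
                bird_id="b1", age=5, round_id=1):
    """Convenience BirdDayStream for unit tests."""
    times = np.asarray(times, dtype=np.int64)
    antennas = np.asarray(antennas, dtype=np.int64)
    if segments is None:
        segments = np.zeros(times.size, dtype=np.int64)
    return BirdDayStream(bird_id=bird_id, round_id=round_id, age_days=age,
                         date=dt.date(2021, 3, 5), times=times, antennas=antennas,
                         segments=np.asarray(segments, dtype=np.int64),
                         effective_seconds=effective_seconds)


def make_records(rows):
    """Registration DataFrame from (iso_time, tag, antenna) tuples."""
    return pd.DataFrame({
        "time": pd.to_datetime([r[0] for r in rows]),
        "tag_id": [r[1] for r in rows],
        "antenna_id": np.asarray([r[2] for r in rows], dtype=np.int64),
    }).sort_values("time", kind="stable").reset_index(drop=True)


def one_round(start_age=1, end_age=20, n_birds=2, start=dt.date(2021, 3, 4)):
    return RoundSpec(1, start_age, end_age, n_birds, start)
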