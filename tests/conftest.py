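import numpy as np
import pandas as pd
import pytest

from osmopulse import EnvRateMap, SimConfig, make_schedule, simulate_chamber


def make_table(rows):
    """Build a tracking table from (fov, frame, time, oid, parent, x, y, size, dead) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["fov", "frame", "time", "object_id", "parent_id", "x", "y", "size", "dead"],
    )
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df


@pytest.fixture
def ips96():
    return make_schedule("IPS", period=96, total_duration=60 + 4 * 96)


@pytest.fixture
def as96():
    return make_schedule("AS", period=96, total_duration=60 + 4 * 96)


@pytest.fixture(scope="session")
def homogeneous_run():
    """One moderate constant-environment simulation shared across tests."""
    schedule = make_schedule("constant", total_duration=720)
    cfg = SimConfig(
        initial_cells=120,
        division_rate_map=EnvRateMap.constant(0.005),
        seed=42,
    )
    table, truth = simulate_chamber(cfg, schedule)
    return table, truth, schedule, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
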