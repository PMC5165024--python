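import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spikeprop as sp

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid8() -> sp.ElectrodeMap:
    """8x8 subdural grid at 10 mm pitch, channels 1..64."""
    return sp.ElectrodeMap.from_grid(8, 8)


@pytest.fixture(scope="session")
def weights8(grid8) -> sp.SpatialWeights:
    return sp.spatial_weights(grid8)


@pytest.fixture()
def two_channel_map() -> sp.ElectrodeMap:
    return sp.ElectrodeMap(pd.DataFrame({
        "channel_id": [1, 2], "label": ["a", "b"],
        "x_mm": [0.0, 10.0], "y_mm": [0.0, 0.0],
    }))


def make_dataset(channels, times_ms, minutes=None, **kw) -> sp.SpikeDataset:
    return sp.from_events(channels, times_ms, analyzed_minutes=minutes, **kw)


def make_sequence(channel_time_pairs) -> sp.SpikeSequence:
    chans, times = zip(*channel_time_pairs)
    ev = pd.DataFrame({"channel_id": list(chans), "time_ms": list(times)})
    return sp.SpikeSequence(ev)


@pytest.fixture()
def seq_factory():
    return make_sequence


@pytest.fixture()
def ds_factory():
    return make_dataset


def random_event_stream(rng, n_events, n_channels=16, t_max=2000.0):
    """Small random detector stream for oracle-equivalence checks."""
    ch = rng.integers(1, n_channels + 1, size=n_events)
    t = np.sort(rng.uniform(0, t_max, size=n_events))
    return sp.from_events(ch, t, analyzed_minutes=max(t_max / 60000.0, 1e-6))
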