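import numpy as np
import pandas as pd
import pytest

from seizurecast.record_store import MinuteRecord, SeizureCatalog
from seizurecast.synthetic_eeg import SimConfig


def make_minute(
    start="2024-01-01 00:00",
    n_channels=4,
    sample_rate=100.0,
    seed=0,
    missing=None,
    data=None,
):
    """A single MinuteRecord of white noise with an optional missing block.

    ``missing`` is a (channel, start_sample, n_samples) triple.
    """
    rng = np.random.default_rng(seed)
    n = round(60 * sample_rate)
    if data is None:
        data = rng.standard_normal((n_channels, n))
    mask = np.zeros_like(data, dtype=bool)
    if missing is not None:
        ch, i0, ln = missing
        mask[ch, i0 : i0 + ln] = True
        data = data.copy()
        data[mask] = np.nan
    return MinuteRecord(
        start_time=pd.Timestamp(start),
        sample_rate=sample_rate,
        data=data,
        missing_mask=mask,
    )


@pytest.fixture
def desk_sim_config():
    """Small-but-real synthetic recording config used across tests."""
    return SimConfig(
        n_channels=4,
        sample_rate=100.0,
        duration_days=1,
        seizure_rate=4.0,
        preictal_mode="marker",
        preictal_horizon=15.0,
        dropout_rate=2.0,
        seed=7,
    )


@pytest.fixture
def toy_catalog():
    """Seizures at 0 h, 3 h and 10 h from the epoch (second one non-lead)."""
    base = pd.Timestamp("2024-01-01")
    return SeizureCatalog(
        pd.DatetimeIndex(
            [base, base + pd.Timedelta(hours=3), base + pd.Timedelta(hours=10)]
        )
    )
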