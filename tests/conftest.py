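import numpy as np
import pandas as pd
import pytest

from bracewear.config import DetectConfig, SimConfig


@pytest.fixture
def quiet_sim() -> SimConfig:
    """Deterministic physics: no noise, no diurnal cycle, no confounders,
    no between-participant heterogeneity."""
    return SimConfig(
        n_participants=2,
        n_days=3,
        sensor_noise_sd=0.0,
        ambient_diurnal_amp=0.0,
        confounder_rate=0.0,
        quantization=0.0,
        p_wear_day_between_sd=0.0,
        bout_mean_between_sd=0.0,
        report_gain_between_sd=0.0,
        seed=7,
    )


@pytest.fixture
def detect_defaults() -> DetectConfig:
    return DetectConfig()


def constant_series(pid="P01", temp=22.0, n=145, interval=10, start="2024-01-01"):
    from bracewear.types import TemperatureSeries

    ts = pd.date_range(start, periods=n, freq=f"{interval}min")
    return TemperatureSeries(pid, ts, np.full(n, temp))
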