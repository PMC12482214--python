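import numpy as np
import pytest

from mcsv.synthetic import SimulationConfig, simulate_record


@pytest.fixture(scope="session")
def small_record():
    """Three-channel 2-minute record with one seizure at 100 s."""
    cfg = SimulationConfig(
        duration=120.0,
        seizure_onsets=[100.0],
        pil_minutes=1.0,
        n_channels=3,
        ictal_s=20.0,
        seed=11,
    )
    record, truth = simulate_record(cfg)
    return record, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """FFT periodogram band power oracle used across tests."""
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    power = np.abs(np.fft.rfft(x)) ** 2 / len(x)
    return float(power[(freqs >= lo) & (freqs <= hi)].sum())
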