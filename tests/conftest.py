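import logging

import numpy as np
import pytest

from fogsync.synthetic import SimConfig, generate_session


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    """Exercise warning paths without spamming the test output."""
    logging.getLogger("fogsync").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """One 30 s trial, reduced montage (2 strip + 2x2 depth contacts), 1 kHz."""
    return SimConfig(
        trial_duration=30.0,
        neural_rate_hz=1000.0,
        n_strip_contacts=2,
        n_depth_contacts=2,
        fog_episodes_per_trial=1,
        fog_duration_range=(6.0, 9.0),
        subject_effect_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    session, truth = generate_session(small_config, "S01", "T01")
    return session, truth


def brute_force_band_power(x: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    """Independent oracle: Hann-tapered DFT by explicit summation, band sum.

    Band membership is half-open on bin centres, matching the freeze-index
    convention.
    """
    n = len(x)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
    xw = x * w
    total = 0.0
    for k in range(n // 2 + 1):
        f = k * rate / n
        if band[0] <= f < band[1]:
            c = np.sum(xw * np.exp(-2j * np.pi * k * np.arange(n) / n))
            total += np.abs(c) ** 2
    return total
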