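import numpy as np
import pytest

import lpfsc


@pytest.fixture(scope="session")
def vessel_clean_frame():
    """Clean simulated frame of the default in-silico setup (shared)."""
    phantom = lpfsc.make_vessel_phantom(512, seed=1)
    geometry = lpfsc.circular_array()
    frame = lpfsc.forward_simulate(phantom, geometry, lpfsc.AcquisitionSpec())
    return phantom, geometry, frame


def make_test_signal(seed: int, n: int = 256, snr_db: float = 0.0):
    """Low-frequency baseline + sparse blocks + white noise, with the clean
    signal returned alongside (the solver's generative model)."""
    r = np.random.default_rng(seed)
    t = np.arange(n)
    clean = 0.8 * np.sin(2 * np.pi * t / n * 1.5 + r.uniform(0, 6))
    for _ in range(6):
        i = int(r.integers(10, n - 18))
        w = int(r.integers(3, 9))
        clean[i : i + w] += r.uniform(0.8, 2.0) * r.choice([-1.0, 1.0])
    sigma = np.sqrt(np.mean(clean**2) * 10 ** (-snr_db / 10))
    return clean, clean + sigma * r.standard_normal(n)
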