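import numpy as np
import pytest

from glycoecg import SynthesisParams, synthesize_ecg


@pytest.fixture(scope="session")
def noise_free_record():
    """8-s, 60 bpm, zero-dispersion, disturbance-free record + truth."""
    params = SynthesisParams(
        mean_hr=60.0, sdnn=0.0,
        baseline_amp=0.0, powerline_amp=0.0, white_noise_sd=0.0, seed=11,
    )
    return synthesize_ecg(params)


@pytest.fixture(scope="session")
def noisy_record():
    """Default-disturbance record (baseline 0.3, 60 Hz 0.1, noise 0.02)."""
    return synthesize_ecg(SynthesisParams(mean_hr=72.0, sdnn=0.03, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_uniform_record(path, n, fs=1400.0, amplitudes=None, sep=" "):
    """Helper: write an n-row two-column text record at uniform spacing."""
    t = np.arange(n) / fs
    x = amplitudes if amplitudes is not None else np.sin(2 * np.pi * 5 * t)
    with open(path, "w") as fh:
        fh.write("# synthetic test record\n")
        for ti, xi in zip(t, x):
            fh.write(f"{ti:.9f}{sep}{xi:.6f}\n")
    return path
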