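import numpy as np
import pytest

from ecgkit.synthetic import BeatTemplate, SimulationConfig, generate_ecg


@pytest.fixture
def clean_config():
    """Noise-free 60 bpm record: beats land exactly one second apart."""
    return SimulationConfig(fs=360.0, duration=30.0, heart_rate=60.0,
                            rr_jitter_sd=0.0, seed=7)


@pytest.fixture
def clean_record(clean_config):
    return generate_ecg(clean_config)


@pytest.fixture
def default_template():
    return BeatTemplate()


def match_peaks(detected, truth, fs, window_s=0.05):
    """Count ground-truth peaks matched by a detection within the window."""
    detected = np.asarray(detected)
    if detected.size == 0:
        return 0
    w = window_s * fs
    matched = 0
    for t in np.asarray(truth):
        if np.min(np.abs(detected - t)) <= w:
            matched += 1
    return matched


@pytest.fixture
def peak_matcher():
    return match_peaks
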