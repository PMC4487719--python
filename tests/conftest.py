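import numpy as np
import pytest

from mrcpdetect import (SimulationConfig, generate_recording, make_surrogate,
                        resolve_onsets)


@pytest.fixture(scope="session")
def small_cfg():
    """A cheap but otherwise default-shaped protocol (10 trials per task)."""
    return SimulationConfig(n_trials_per_task=10, seed=42)


@pytest.fixture(scope="session")
def real_recording(small_cfg):
    return generate_recording(small_cfg, "real", subject_id="S1")


@pytest.fixture(scope="session")
def imaginary_recording(small_cfg):
    return generate_recording(small_cfg, "imaginary", subject_id="S2")


@pytest.fixture(scope="session")
def real_surrogate(real_recording):
    return make_surrogate(real_recording.eeg, real_recording.channels,
                          real_recording.fs_eeg)


@pytest.fixture(scope="session")
def real_onsets(real_recording):
    return resolve_onsets(real_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
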