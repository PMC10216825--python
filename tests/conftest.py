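import numpy as np
import pytest
from hypothesis import settings

from gcq import RecordingSet, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recordings() -> RecordingSet:
    """2 subjects × 4 trials (one per class), short trials, fixed seed."""
    return generate_dataset(
        n_subjects=2, n_trials_per_subject=4, seed=11, n_samples=512
    )


@pytest.fixture(scope="session")
def medium_recordings() -> RecordingSet:
    """4 subjects × 20 balanced trials for classification-level tests."""
    return generate_dataset(
        n_subjects=4, n_trials_per_subject=20, seed=11, n_samples=1024
    )
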