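import logging

import numpy as np
import pytest

from gastromill.core import AnalysisConfig
from gastromill.synth import RhythmSpec, generate_condition_batch, generate_recording

# keep expected-degenerate-input warnings out of the test log
logging.getLogger("gastromill").setLevel(logging.ERROR)


@pytest.fixture()
def cfg() -> AnalysisConfig:
    return AnalysisConfig(rng_seed=0)


@pytest.fixture(scope="session")
def full_recording():
    return generate_recording(RhythmSpec(state="FULL", seed=7))


@pytest.fixture(scope="session")
def irregular_recording():
    return generate_recording(RhythmSpec(state="IRREGULAR", seed=11))


@pytest.fixture(scope="session")
def none_recording():
    return generate_recording(RhythmSpec(state="NONE", seed=5))


@pytest.fixture(scope="session")
def balanced_batch():
    """20 subjects, states balanced across FULL / IRREGULAR / NONE."""
    mix = {"FULL": 1 / 3, "IRREGULAR": 1 / 3, "NONE": 1 / 3}
    return generate_condition_batch(20, mix, seed=11)


def random_train_times(rng: np.random.Generator, n_max: int = 60) -> np.ndarray:
    """Random strictly-increasing spike times with mixed gap scales."""
    n = rng.integers(2, n_max)
    gaps = rng.choice([0.02, 0.1, 0.3, 1.0, 2.5], size=n) * rng.uniform(
        0.5, 1.5, size=n)
    return np.cumsum(gaps)
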