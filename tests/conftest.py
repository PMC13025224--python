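import numpy as np
import pytest
from hypothesis import settings

from eegtfr.synthetic import SyntheticCohortSpec, ToneSpec, generate_cohort, generate_tones

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def two_tone_signal():
    """Noiseless 5 + 40 Hz test signal at 512 Hz, 15 s."""
    spec = ToneSpec(frequencies=[5.0, 40.0], fs=512.0, duration_s=15.0)
    return generate_tones(spec), spec


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 2R/2NR cohort (60 s at 256 Hz) shared across tests."""
    spec = SyntheticCohortSpec(n_responders=2, n_nonresponders=2,
                               duration_s=60.0, fs=256.0, seed=11)
    return generate_cohort(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
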