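import numpy as np
import pytest

from vfshock import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Calibrated default cohort, 200 patients, no waveforms (fast)."""
    return generate_cohort(GeneratorConfig(n_patients=200, seed=42,
                                           include_episodes=False))


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    return default_cohort.to_frame()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
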