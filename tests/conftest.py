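import numpy as np
import pytest

from dfcfp import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-subject, 12-region cohort shared by the faster module tests."""
    return generate_cohort(SynthConfig(nsub=8, r=12, T=240, seed=7))
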