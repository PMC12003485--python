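import numpy as np
import pytest

from meromix import LakeScenario, gen_ctd_profile


@pytest.fixture
def clean_cast():
    """Noise-free default stratified cast on a 0.1 m grid."""
    return gen_ctd_profile(LakeScenario(noise_sd={}), grid_step=0.1)


@pytest.fixture
def noisy_cast():
    """Default stratified cast with realistic sensor noise."""
    return gen_ctd_profile(LakeScenario(seed=42), grid_step=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
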