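import numpy as np
import pytest

from neuroraman.synth import SyntheticDesign


@pytest.fixture
def design() -> SyntheticDesign:
    """Default study design, fixed seed."""
    return SyntheticDesign(seed=0)


@pytest.fixture
def clean_design() -> SyntheticDesign:
    """Deterministic design: no noise, no spikes, no cell jitter."""
    return SyntheticDesign(noise_scale=0.0, spike_rate=0.0,
                           amplitude_jitter=0.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
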