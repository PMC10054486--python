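import numpy as np
import pytest

from agbmap.synthgen import SyntheticSpec, generate_scene


@pytest.fixture(scope="session")
def small_pair():
    """A 64×64 synthetic scene/AGB pair at 100 m with mild noise."""
    spec = SyntheticSpec(height=64, width=64, seed=11, agb_noise_sd=5.0,
                         nodata_fraction=0.01)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def clean_pair():
    """A fully valid, noiseless 64×64 pair (exact biomass function)."""
    spec = SyntheticSpec(height=64, width=64, seed=7, agb_noise_sd=0.0,
                         band_noise_sd=0.0, nodata_fraction=0.0)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
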