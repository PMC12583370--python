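import numpy as np
import pytest

from mitomorph import synthetic as syn


@pytest.fixture(scope="session")
def small_network():
    """A 12-branch / 4-junction / 3-rod network on a 256x256 grid."""
    return syn.generate_network(12, 4, 3, seed=7)


@pytest.fixture(scope="session")
def noiseless_field(small_network):
    """Noiseless, background-free rendering of the small network."""
    return syn.render_field(
        small_network,
        render_spec=syn.RenderSpec(noise_sd=0.0, background_level=0.0, seed=0),
    )


@pytest.fixture(scope="session")
def noisy_field(small_network):
    """Default-noise rendering (background 10, Gaussian sd 5)."""
    return syn.render_field(small_network, render_spec=syn.RenderSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
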