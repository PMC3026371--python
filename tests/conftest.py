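import numpy as np
import pytest

import dermoseg as d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Small noise-free phantom with exact two-level contrast."""
    spec = d.PhantomSpec(
        nc=240,
        nr=180,
        semi_axes=(60.0, 42.0),
        noise_sigma=0.0,
        n_hairs=0,
        n_bubbles=0,
        seed=11,
    )
    return d.make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Full-size phantom at the default noisy conditions."""
    return d.make_phantom(d.preset_spec("noisy", seed=3))
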