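import numpy as np
import pytest

from btrkit.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_phantom_pair():
    """Seed-0 tumor phantom at noise sigma 0.05 plus its clean rendering."""
    spec = PhantomSpec(noise_sigma=0.05, seed=0)
    noisy, mask, label = generate_phantom(spec)
    clean, _, _ = generate_phantom(PhantomSpec(noise_sigma=0.0, seed=0))
    return noisy, clean, mask, label
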