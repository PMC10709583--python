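import numpy as np
import pytest

from aortacine.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_study():
    """One deterministic default phantom study (cine, masks, truth)."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
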