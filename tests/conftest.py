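import numpy as np
import pytest

from hippseg.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One deterministic 6-class two-modality phantom shared across tests."""
    return generate_phantom(PhantomSpec(rng_seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
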