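import numpy as np
import pytest

from tvac import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def clean_phantom(default_spec):
    """One clean default phantom, shared read-only across tests."""
    return generate_phantom(default_spec, 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
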