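import numpy as np
import pytest

from cxrseg import PhantomSpec, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64 phantom with moderate noise."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 64x64 phantoms for pipeline-level tests."""
    return generate_dataset(8, PhantomSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
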