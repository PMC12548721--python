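import pytest

from electrum import generate_complexes


@pytest.fixture(scope="session")
def synthetic_500():
    """Shared 500-complex synthetic dataset (fixed seed)."""
    return generate_complexes(500, seed=11)


@pytest.fixture(scope="session")
def synthetic_50():
    """Small synthetic dataset for fast unit tests."""
    return generate_complexes(50, seed=23)
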