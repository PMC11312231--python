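import numpy as np
import pytest

from perioloc.synthetic import SceneParams, generate_case, generate_suite


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_case():
    """Untilted, uncorrupted default scene."""
    return generate_case(SceneParams())


@pytest.fixture(scope="session")
def suite100():
    """The standard 100-case evaluation suite (shared across tests)."""
    return generate_suite(100, seed=42)
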