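import numpy as np
import pytest

from acnedet.synthetic import easy_spec, generate_images


@pytest.fixture(scope="session")
def easy_images():
    """Twenty low-density synthetic images shared by cheap tests."""
    return generate_images(20, easy_spec(), seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
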