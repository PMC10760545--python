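import numpy as np
import pytest

from punctaline import DetectionParams, generate, standard_fixture_spec

#: detection settings tuned for the uncalibrated standard fixture (areas in px²)
FIXTURE_PARAMS = DetectionParams(min_size=5, sigma=1.0, radius=6)


@pytest.fixture(scope="session")
def standard_fixture():
    """(image, truth) for the well-resolved 20-punctum reference fixture."""
    return generate(standard_fixture_spec(seed=1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
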