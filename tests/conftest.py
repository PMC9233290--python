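import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fundustk import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-resolution spec so generation stays fast in unit tests."""
    return synth.ImageSpec(width=224, height=224)


@pytest.fixture(scope="session")
def sample_images(small_spec):
    """One generated image per grade, shared across tests."""
    return {
        grade: synth.generate_image(small_spec, grade, seed=100 + grade)
        for grade in range(5)
    }
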