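import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=100)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_table():
    """Feature table of the default phantom experiment (48 balanced pairs)."""
    from cesmcad.features import extract_table
    from cesmcad.synthetic import PhantomConfig, generate_dataset

    return extract_table(generate_dataset(PhantomConfig(seed=1)))


@pytest.fixture(scope="session")
def noise_phantom_table():
    """Feature table of lesion-free phantoms (lesion contrast 0)."""
    from cesmcad.features import extract_table
    from cesmcad.synthetic import PhantomConfig, generate_dataset

    return extract_table(
        generate_dataset(PhantomConfig(lesion_contrast=0.0, seed=2)))
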