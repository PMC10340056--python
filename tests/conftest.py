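import numpy as np
import pytest

from histotune.synth import SyntheticSpec, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def easy_dataset():
    """Small, well-separated 5-class synthetic set (difficulty 0.1)."""
    return generate_dataset(
        SyntheticSpec(images_per_class=24, image_size=16, difficulty=0.1, seed=7)
    )


@pytest.fixture(scope="session")
def easy_split(easy_dataset):
    return split_dataset(easy_dataset, 0.8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
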