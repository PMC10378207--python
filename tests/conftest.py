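import numpy as np
import pytest

from mexflow import SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """Small separable 3-class spec used by training-related tests."""
    return SyntheticSpec(
        n_classes=3, samples_per_class=(8, 8, 8), n_subjects=4,
        image_size=(68, 56), seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return make_dataset(tiny_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
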