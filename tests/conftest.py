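import numpy as np
import pytest

from gpcircuit import GammaPoissonParams, make_rectangle_classes, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_params(rng):
    """A small well-behaved two-class model."""
    W = rng.dirichlet(np.ones(5), size=2)
    return GammaPoissonParams.create(W=W, alpha=[4.0, 6.0], beta=[0.5, 0.2])


@pytest.fixture(scope="session")
def rect_params():
    """Three rectangle classes with mean intensities 50, 150, 300."""
    return make_rectangle_classes(3, 5, [2, 3, 4], seed=7, lam=[50.0, 150.0, 300.0])


@pytest.fixture(scope="session")
def rect_data(rect_params):
    return sample_dataset(rect_params, 2000, seed=11)
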