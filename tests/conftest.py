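import numpy as np
import pytest

from dirqa.phantom import PhantomConfig, PlanPrescription, build_dose_model, generate_phantom


@pytest.fixture(scope="session")
def phantom96():
    """Default phantom: 96^3 @ 2 mm, seed 7."""
    return generate_phantom(PhantomConfig(), seed=7)


@pytest.fixture(scope="session")
def phantom_small():
    """Coarse phantom for fast unit tests: 48^3 @ 3 mm."""
    return generate_phantom(PhantomConfig(shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0)), seed=7)


@pytest.fixture(scope="session")
def rx_two_level():
    return PlanPrescription([4500.0, 7500.0])


@pytest.fixture(scope="session")
def dose_model_small(phantom_small, rx_two_level):
    _, structures = phantom_small
    return build_dose_model(structures, rx_two_level)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
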