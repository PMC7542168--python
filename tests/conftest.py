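import numpy as np
import pytest

from textrisk.calibration import default_calibration
from textrisk.cohort import generate_cohort


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def oracle_cohort(calibration):
    """Small oracle-mode cohort shared across read-only tests."""
    return generate_cohort(calibration, 400, seed=42, mode="oracle",
                           embed_dim=32)


@pytest.fixture(scope="session")
def text_cohort(calibration):
    """Small text-mode cohort shared across read-only tests."""
    return generate_cohort(calibration, 120, seed=7, mode="text")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
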