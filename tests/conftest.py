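import numpy as np
import pytest

from omenscreen.synthetic import default_calibration, generate_cohort


@pytest.fixture(scope="session")
def moment_spec():
    return default_calibration("moment")


@pytest.fixture(scope="session")
def quantile_spec():
    return default_calibration("quantile")


@pytest.fixture(scope="session")
def cohort134(moment_spec):
    """Default-calibration cohort at the published group sizes (56 + 78)."""
    return generate_cohort(moment_spec, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
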