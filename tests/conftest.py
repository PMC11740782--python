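import numpy as np
import pytest

from usexpand import desk_config, generate_cohort

MIX = {"normal": 1 / 3, "benign": 1 / 3, "malignant": 1 / 3}


@pytest.fixture(scope="session")
def small_config():
    """32-px phantom parameters used across fast tests."""
    return desk_config(seed=0, image_side=32)


@pytest.fixture(scope="session")
def standard_cohort(small_config):
    return generate_cohort(20, (2, 2), MIX, "standard", small_config, seed=301,
                           patient_prefix="std")


@pytest.fixture(scope="session")
def pocus_cohort(small_config):
    return generate_cohort(20, (2, 2), MIX, "pocus", small_config, seed=302,
                           patient_prefix="poc")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
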