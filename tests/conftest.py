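import numpy as np
import pytest

from rehabmech.activity import FEATURE_NAMES
from rehabmech.synthetic import simulate_feature_cohort


@pytest.fixture(scope="session")
def goldilocks_xy():
    """Planted goldilocks feature cohort: (X, y) at the default size."""
    cohort = simulate_feature_cohort(60, seed=11)
    X = cohort[list(FEATURE_NAMES)].to_numpy()
    y = cohort["bone_volume"].to_numpy()
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
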