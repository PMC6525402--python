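import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pcotex as pt

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRAIN_SEED = 101


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def train_scenes():
    scenes, _ = pt.generate_dataset(12, seed=TRAIN_SEED)
    return scenes


@pytest.fixture(scope="session")
def trained_grader(train_scenes):
    """Grader fitted once on the training dataset; reused across tests."""
    return pt.PCOGrader(random_state=TRAIN_SEED).fit(train_scenes)
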