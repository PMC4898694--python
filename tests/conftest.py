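import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from matesim.config import ModelConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def tiny_config():
    """Two-algorithm model small enough for fast end-to-end runs."""
    return ModelConfig(
        n_agents=40,
        pop_cap=60,
        n_generations=5,
        algorithm_roster=(("euclidean", 10), ("polynomial", 10)),
    )
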