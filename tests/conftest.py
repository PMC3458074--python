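import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A fast study configuration on a small symmetric grid."""
    from hemiconn import SimulationConfig

    return SimulationConfig(
        grid_dims=(12, 10, 8), n_timepoints=60,
        n_per_group={"control": 6, "patient": 6},
        dti_n_per_group={"control": 8, "patient": 8},
        rng_seed=11,
    )
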