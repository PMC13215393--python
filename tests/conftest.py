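import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """A 20-sample, 8-SNP case/control dataset."""
    from provgen.synthetic import generate_case_control

    return generate_case_control(
        m=8, n_case=10, n_control=10, causal_indices=[0], effect_or=3.0, seed=7
    ).dataset
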