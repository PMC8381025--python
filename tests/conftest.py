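import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_form():
    """One 300-person form of the four-strand design, for cheap end-to-end tests."""
    from strandmastery import SimulationCondition, generate_form

    cond = SimulationCondition(n_persons=300, rho=0.3, n_forms=1, seed=42)
    return generate_form(cond, 0)
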