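import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import arsurv as av

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_sample() -> av.CohortSample:
    """Ten hand-checkable subjects; unexposed KM steps are 4/5, 8/15, 4/15."""
    time = [1, 2, 3, 4, 5, 2, 4, 5, 6, 8]
    event = [1, 0, 1, 1, 0, 1, 1, 1, 0, 1]
    exposure = [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
    return av.CohortSample(np.array(time, float), np.array(event), np.array(exposure))


@pytest.fixture(scope="session")
def ph_sample() -> av.CohortSample:
    """One moderate proportional-hazards cohort (γ=1, β=ln 2, q=0.5, n=2,000)."""
    config = av.ScenarioConfig(model="PH", n=2000, seed=42)
    return av.generate_ph(config, av.replicate_rng(42, 0))


@pytest.fixture(scope="session")
def nph_sample() -> av.CohortSample:
    config = av.ScenarioConfig(model="NPH", n=2000, seed=43)
    return av.generate_nph(config, av.replicate_rng(43, 0))
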