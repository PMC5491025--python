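import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def small_structure():
    from sbcc import PopulationStructure

    return PopulationStructure.uniform(2, 0.005)


@pytest.fixture
def small_design():
    from sbcc import CohortDesign

    return CohortDesign.balanced(200, 2)
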