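import pytest
from hypothesis import HealthCheck, settings

from gmfa.network import GeneralizedStoichiometry, example_diabetes_map

from .helpers import make_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def diabetes_map() -> GeneralizedStoichiometry:
    return example_diabetes_map()


@pytest.fixture()
def two_node_model() -> GeneralizedStoichiometry:
    """A -> B with unit coefficients: S = [[-1], [1]]."""
    return make_model([[-1.0], [1.0]], lb=[0.0], ub=[2.0])
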