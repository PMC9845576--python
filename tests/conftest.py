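import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20230104)


@pytest.fixture(scope="session")
def adjusted_endmembers():
    """Default endmember table water-adjusted to -8.5 permil, plus epsilons."""
    from n2osource.endmembers import default_endmembers

    ems, eps = default_endmembers()
    return ems.adjust_for_water(-8.5), eps


@pytest.fixture
def truth_config():
    from n2osource.synthetic import TruthConfig

    return TruthConfig()
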