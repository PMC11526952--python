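import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gdforecast import Params, build_lattice, equilibrium_diversity

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid4():
    return build_lattice(4, 4)


@pytest.fixture(scope="session")
def params_small():
    """Desk-scale rates: theta small, moderate structure on a 4x4 grid."""
    return Params(mu=1e-7, deme_size=50.0, mig=0.05)


@pytest.fixture(scope="session")
def eq4(grid4, params_small):
    return equilibrium_diversity(grid4, params_small)
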