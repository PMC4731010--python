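import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plux_params():
    from orthosignal.defaults import promoter_params
    return promoter_params("pLux")


@pytest.fixture(scope="session")
def device_fixture():
    """Two-channel device at the optimized receiver levels."""
    from orthosignal.defaults import OPTIMAL_DEVICE_LEVELS, promoter_params
    from orthosignal.design_optimizer import TwoChannelDevice
    r, s = OPTIMAL_DEVICE_LEVELS
    return TwoChannelDevice(promoter_params("pLux76", r=r, s=s),
                            promoter_params("pLas81", r=r, s=s))


@pytest.fixture(scope="session")
def spatial_params():
    from orthosignal.spatial_sim import SpatialParameters
    return SpatialParameters()


def random_crosstalk_params(rng):
    """A random parameter set in the physically sensible regime."""
    from orthosignal.core_model import CrosstalkParameters
    return CrosstalkParameters(
        KR6=10 ** rng.uniform(-4, -1), KR12=10 ** rng.uniform(-6, -3),
        KS6=10 ** rng.uniform(-9, -6), KS12=10 ** rng.uniform(-4, -1),
        KGR=10 ** rng.uniform(-1, 1), KGS=10 ** rng.uniform(-2, 0),
        a0=10 ** rng.uniform(-2, 0), a1R=10 ** rng.uniform(0, 1.5),
        a1S=10 ** rng.uniform(0, 1.5), n=2.0,
        r=10 ** rng.uniform(-0.5, 1), s=10 ** rng.uniform(-0.5, 1))
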