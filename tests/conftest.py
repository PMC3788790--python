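import numpy as np
import pytest

from dcewall import AcquisitionProtocol, ParkerAif, make_time_grid


@pytest.fixture(scope="session")
def protocol():
    """Default vessel-wall protocol: 25 dynamics, 18 s, injection at dynamic 6."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def times_s(protocol):
    return make_time_grid(protocol, seed=0)


@pytest.fixture(scope="session")
def times_min(times_s):
    return times_s / 60.0


@pytest.fixture(scope="session")
def aif(protocol, times_s):
    """Population slow-injection AIF with onset at the injection dynamic."""
    return ParkerAif.population_slow_injection(t0=times_s[protocol.injection_dynamic - 1] / 60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
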