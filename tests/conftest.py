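import numpy as np
import pytest
from hypothesis import settings

from timeshifts import WDistribution

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


SIR_BETA, SIR_GAMMA = 0.95, 0.5
SIR_Q = SIR_GAMMA / SIR_BETA
SEIR_PARAMS = (0.56, 0.5, 0.33)


@pytest.fixture(scope="session")
def sir_pair():
    from timeshifts import fixtures

    return fixtures.sir()


@pytest.fixture(scope="session")
def seir_pair():
    from timeshifts import fixtures

    return fixtures.seir()


@pytest.fixture(scope="session")
def innate_pair():
    from timeshifts import fixtures

    return fixtures.innate()


@pytest.fixture(scope="session")
def sir_wd(sir_pair) -> WDistribution:
    return WDistribution(sir_pair[0], [1])


@pytest.fixture(scope="session")
def seir_wd(seir_pair) -> WDistribution:
    return WDistribution(seir_pair[0], [1, 0])


@pytest.fixture()
def rng(request):
    # per-test deterministic stream, independent of execution order
    seed = int.from_bytes(request.node.name.encode(), "little") % (2**31)
    return np.random.default_rng(seed)
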