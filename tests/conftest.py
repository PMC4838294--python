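import numpy as np
import pytest

import hpolsim as h


@pytest.fixture(scope="session")
def params():
    return h.default_parameters()


@pytest.fixture(scope="session")
def baseline():
    """Full one-cycle baseline simulation with the packaged driver (shared)."""
    return h.simulate(options=h.SimulationOptions(duration_days=365.0))


@pytest.fixture(scope="session")
def short_run():
    """Cheap 40-day run for structural checks (no ovulation expected)."""
    return h.simulate(options=h.SimulationOptions(duration_days=40.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
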