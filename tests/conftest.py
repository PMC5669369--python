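import numpy as np
import pytest

from tadsim import (
    compile_scenario,
    default_params,
    integrate,
    struggle_protocol,
    swim_protocol,
)
from tadsim.simulate import NoiseProcess


def zero_noise():
    return NoiseProcess(np.zeros(10), 1.0, seed=0)


@pytest.fixture()
def params():
    """A fresh copy of the calibrated default parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def swim_run():
    """Deterministic swim-initiation simulation (shared across tests)."""
    p = default_params()
    stim = compile_scenario(swim_protocol(duration=3000.0), p)
    return integrate(p, stim, dt=0.1, noise=zero_noise(), controllers_enabled=False)


@pytest.fixture(scope="session")
def struggle_run():
    """Deterministic struggle simulation entered from ongoing swimming."""
    p = default_params()
    stim = compile_scenario(struggle_protocol(duration=3200.0, from_swimming=True), p)
    return integrate(p, stim, dt=0.1, noise=zero_noise(), controllers_enabled=False)
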