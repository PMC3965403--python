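import numpy as np
import pytest

from delayosc import (
    HistoryFunction,
    calibrate_to_equilibrium,
    integrate_dde,
)


@pytest.fixture(scope="session")
def mono_nonsat_spec():
    """Monotonic + linear-degradation model calibrated to x* = 1, in its
    robust oscillatory regime."""
    return calibrate_to_equilibrium(
        "monotonic", "non_saturable", n=10, tau=5.0, x_target=1.0, gamma=1.0
    )


@pytest.fixture(scope="session")
def mono_sat_spec():
    return calibrate_to_equilibrium(
        "monotonic", "saturable", n=10, tau=5.0, x_target=1.0, gamma=1.0
    )


@pytest.fixture(scope="session")
def mono_nonsat_ts(mono_nonsat_spec):
    """A settled oscillatory trajectory reused across metric tests."""
    return integrate_dde(
        mono_nonsat_spec, HistoryFunction(value=1.1), t_end=400.0, dt=1e-3
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
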