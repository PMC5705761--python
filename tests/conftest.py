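import numpy as np
import pytest

from ratchetdl import Potential, SimulationParams

TWO_PI = 2 * np.pi


@pytest.fixture
def free_params():
    """Free-particle configuration (no potential, no drive)."""
    def make(**kw):
        defaults = dict(
            m=6.0, a=0.0, omega=0.403, theta=0.1, phi=np.pi / 2,
            steps_per_period=200, t_max=100.0, n_traj=256, seed=1234,
            potential=Potential(scale=0.0),
        )
        defaults.update(kw)
        return SimulationParams(**defaults)
    return make


@pytest.fixture
def ratchet_params():
    """Reference ratchet configuration (m=6, a=1.899, ω=0.403)."""
    def make(**kw):
        defaults = dict(steps_per_period=200, t_max=2000.0, n_traj=128, seed=4321)
        defaults.update(kw)
        return SimulationParams(**defaults)
    return make
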