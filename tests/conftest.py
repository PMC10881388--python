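import numpy as np
import pytest

from trsfx.models import GroundTruthSchedule
from trsfx.scattering import structure_factors
from trsfx.synthetic import TwoStateConfig, build_two_state_system


@pytest.fixture(scope="session")
def system():
    return build_two_state_system(TwoStateConfig())


@pytest.fixture(scope="session")
def schedule():
    return GroundTruthSchedule()


@pytest.fixture(scope="session")
def dark_sf(system):
    """Structure factors of the dark state at the default resolution."""
    return structure_factors(system.dark, d_min=1.4)


@pytest.fixture(scope="session")
def excited_sf(system, dark_sf):
    return structure_factors(system.excited, d_min=1.4, hkl=dark_sf.hkl)


@pytest.fixture()
def mixture_amplitudes(dark_sf, excited_sf):
    """Noise-free observed amplitudes of a two-state mixture at fraction f."""
    def make(f):
        fc = (1.0 - f) * dark_sf.complex_f() + f * excited_sf.complex_f()
        obs = dark_sf.with_f(np.abs(fc))
        obs.phase = None
        return obs
    return make
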