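"""Shared fixtures: synthetic scenes at the standard study conditions.

The standard validation stack is air / bone (1.8 - 0.08i) / glass
(2.6 - 0.15i) probed by a 0.3-1 THz Gaussian pulse.  Fixtures are
module-scoped where synthesis or retrieval is expensive.
"""

import numpy as np
import pytest
from hypothesis import settings

from thzhybrid import (
    KKSettings,
    PulseSpec,
    SyntheticScene,
    bone_on_glass,
    synthesize_waveforms,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

BAND = (0.3e12, 1.0e12)
ANALYSIS_BAND = (0.1e12, 1.6e12)
THZ2 = 2 * np.pi * 1e12


@pytest.fixture(scope="session")
def pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def stack100():
    """The validation stack with a 100 um sample layer."""
    return bone_on_glass(100e-6)


@pytest.fixture(scope="session")
def pair100(pulse, stack100):
    """Sample/reference pair with the reference plane at the glass surface
    (offset = layer thickness = 100 um)."""
    scene = SyntheticScene(stack100, reference_offset=100e-6)
    return synthesize_waveforms(scene, pulse)


@pytest.fixture(scope="session")
def thick_pair(pulse):
    """Optically thick sample layer (2 mm: internal echoes strongly damped)
    with a 200 um plane offset -- the plane-misalignment demonstration."""
    scene = SyntheticScene(bone_on_glass(2e-3), reference_offset=200e-6)
    return synthesize_waveforms(scene, pulse)


@pytest.fixture(scope="session")
def lorentz_band():
    """A causal single-oscillator reflectivity tabulated over 0.2-3 THz.

    The medium follows eps(w) = eps_inf + S w0^2 / (w0^2 - w^2 + i g w)
    in the exp(+iwt) convention; the normal-incidence reflectivity is taken
    with the overall sign that makes the phase vanish at DC.
    """
    w0, g, S, eps_inf = 1.5 * THZ2, 0.6 * THZ2, 0.6, 2.4
    omega = np.linspace(0.2, 3.0, 281) * THZ2
    eps = eps_inf + S * w0**2 / (w0**2 - omega**2 + 1j * g * omega)
    n = np.sqrt(eps)
    n = np.where(np.imag(n) > 0, -n, n)
    r = -(1 - n) / (1 + n)
    return omega, r


@pytest.fixture(scope="session")
def default_kk():
    return KKSettings()
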