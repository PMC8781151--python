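import numpy as np
import pytest

from silksol.scattering import ScatteringCurve, debye_intensity


@pytest.fixture
def q_grid():
    return np.linspace(0.03, 2.0, 240)


@pytest.fixture
def debye_curve(q_grid):
    """Noiseless Debye curve for a 12.5 nm coil."""
    return ScatteringCurve(q_grid, debye_intensity(q_grid, 3.0, 12.5), label="clean")
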