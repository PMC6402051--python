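import numpy as np
import pytest

from pc4dflow import phantom as ph
from pc4dflow.core import AnalysisPlane, RoiContour


@pytest.fixture(scope="session")
def tube_spec():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def pump_program():
    return ph.PumpProgram.half_sine(30.0, 1000.0)


@pytest.fixture(scope="session")
def tube_dataset(tube_spec, pump_program):
    """Noiseless Womersley tube phantom at the default protocol grid."""
    field, truth = ph.simulate_tube_dataset(tube_spec, pump_program)
    return field, truth


@pytest.fixture(scope="session")
def mid_plane(tube_spec):
    return AnalysisPlane.axial(0.0, pixel_spacing=1.0, extent=(40, 40))


@pytest.fixture(scope="session")
def tube_contour(tube_spec):
    return RoiContour.circle(radius=tube_spec.tube_radius)


@pytest.fixture
def rng():
    return np.random.default_rng(20180626)
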