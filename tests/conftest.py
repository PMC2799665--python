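import numpy as np
import pytest

from looplab.io_formats import TimeSeries
from looplab.state_signal import StateSeries
from looplab.synthetic_data import IdealGeometrySpec, build_ideal_geometry


@pytest.fixture(scope="session")
def hairpin12():
    return build_ideal_geometry(IdealGeometrySpec("beta_hairpin", 12))


@pytest.fixture(scope="session")
def extended8():
    return build_ideal_geometry(IdealGeometrySpec("extended", 8))


@pytest.fixture(scope="session")
def ppii8():
    return build_ideal_geometry(
        IdealGeometrySpec("custom_phi_psi", 8, phi=-75.0, psi=140.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_state_series():
    states = np.array([1, 1, 0, 0, 0, 1, 1, 1, 0, 1], dtype=np.int8)
    return StateSeries(dt=1.0, states=states)


@pytest.fixture
def noisy_distance_series(rng):
    vals = 0.6 + 0.2 * rng.standard_normal(5000)
    return TimeSeries(dt=0.1, values=np.abs(vals), label="d", units="nm")
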