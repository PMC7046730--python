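import numpy as np
import pytest

from vasrf.synth import SyntheticHrtfSpec, make_synthetic_hrtf


@pytest.fixture(scope="session")
def hrtf_spec():
    return SyntheticHrtfSpec()


@pytest.fixture(scope="session")
def grid(hrtf_spec):
    """The default 17 x 5 direction synthetic HRIR grid."""
    return make_synthetic_hrtf(hrtf_spec, seed=0)


@pytest.fixture(scope="session")
def horizontal_grid():
    """Fine horizontal-plane grid (5-deg steps) that contains 65 deg."""
    spec = SyntheticHrtfSpec(azimuths_deg=np.arange(-90.0, 91.0, 5.0),
                             elevations_deg=np.array([0.0, 20.0]))
    return make_synthetic_hrtf(spec, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
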