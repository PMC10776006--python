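import numpy as np
import pytest

from dnprf.fitting import GridSpec
from dnprf.stimulus import make_bar_sequence, make_grid


@pytest.fixture(scope="session")
def grid50():
    return make_grid(8.0, 50)


@pytest.fixture(scope="session")
def design50(grid50):
    """Default-geometry bar design on a 50x50 grid (T=160)."""
    return make_bar_sequence(grid50)


@pytest.fixture(scope="session")
def small_design():
    """Cheap design for fitting unit tests: short 8-direction sweep, 40x40 grid."""
    return make_bar_sequence(
        make_grid(8.0, 40),
        steps_per_pass=10,
        blank_frames=2,
    )


@pytest.fixture(scope="session")
def small_gridspec():
    """Trimmed search grid matched to the cheap design (keeps tests fast)."""
    spec = GridSpec.for_extent(8.0)
    spec.eccentricities = np.geomspace(0.5, 6.0, 6)
    spec.polar_angles = np.linspace(0.0, 2 * np.pi, 8, endpoint=False)
    spec.sigmas = np.geomspace(0.3, 3.0, 5)
    return spec
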