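import numpy as np
import pytest

from fillin.protocol import main_experiment_sequence
from fillin.stimulus import GratingParams, PolarGrid
from fillin.synth import SimParams, simulate_bold


@pytest.fixture(scope="session")
def grid():
    """Coarse polar grid (keeps stimulus tests fast; 0.14 deg/px)."""
    return PolarGrid.make(width_px=240, height_px=180, deg_per_px=0.14)


@pytest.fixture(scope="session")
def params():
    return GratingParams()


@pytest.fixture(scope="session")
def sim_roi():
    """One participant's simulated main-experiment ROI (8 runs, 60 voxels)."""
    seq = main_experiment_sequence(seed=11)
    return simulate_bold(seq, SimParams(), seed=12)


@pytest.fixture()
def ring_grid():
    """Synthetic 1-D 'grid' sampling a circle of radius 8 deg very finely."""
    theta = np.linspace(0.0, 360.0, 72001)[None, :-1]
    r = np.full_like(theta, 8.0)
    return PolarGrid(width_px=theta.shape[1], height_px=1, deg_per_px=1.0,
                     origin=(0.0, 0.0), theta=theta, r=r)
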