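import numpy as np
import pytest

from rootflow.fixtures import LOAM, default_spec, make_scenario, reduced_spec
from rootflow.hydraulics import SoilProfile, TabulatedCurve, VanGenuchten
from rootflow.root_uptake import RootUptakeConfig, StressThresholds
from rootflow.solver import Grid


@pytest.fixture
def loam():
    return LOAM


@pytest.fixture
def tab_curve():
    """Simple two-segment tabulated material used by interpolation tests."""
    return TabulatedCurve(
        h_nodes=(-2.0, -1.0, 0.0),
        theta_nodes=(0.25, 0.30, 0.45),
        thetak_nodes=(0.25, 0.30, 0.45),
        k_nodes=(1e-9, 1e-8, 1e-6),
    )


@pytest.fixture
def grid_1m():
    return Grid(nz=20, dz=0.05)


@pytest.fixture
def loam_props(loam, grid_1m):
    return SoilProfile.homogeneous(loam, 1.0).bind(grid_1m)


@pytest.fixture
def thresholds():
    return StressThresholds()


@pytest.fixture
def uptake_cfg():
    return RootUptakeConfig(icps=1, beta=2.0, zr_max=1.0, jthaw=134, jmatur=180)


@pytest.fixture(scope="session")
def reduced_scenario():
    """Coarse 40-day synthetic scenario with its truth run (shared)."""
    return make_scenario(reduced_spec())


@pytest.fixture(scope="session")
def standard_scenario():
    """The 111-day synthetic scenario with its truth run (shared)."""
    return make_scenario(default_spec())


def dry_hydrostatic_state(props, grid, h_top=-200.0):
    """Equilibrium (zero-flow) state: total head uniform, h = h_top + z."""
    from rootflow.solver import State

    h = h_top + grid.z_centers
    theta = props.theta_of_h(h)
    return State(0.0, h, theta)
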