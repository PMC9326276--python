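import numpy as np
import pytest

from slipgait.dynamics import NormalizedParameters
from slipgait.limit_cycle import SweepGrid, find_fixed_points, make_search_point


@pytest.fixture(scope="session")
def walking_point():
    """A search point known to walk periodically (moderate speed)."""
    return make_search_point(0.45, 0.6, 3.5)


@pytest.fixture(scope="session")
def walking_params(walking_point):
    return NormalizedParameters(
        leg_stiffness=walking_point.leg_stiffness,
        touchdown_angle=walking_point.touchdown_angle)


@pytest.fixture(scope="session")
def stable_fixed_points():
    """Stable periodic solutions from a small constraint-F sweep."""
    grid = SweepGrid(v_g0=np.array([0.45]),
                     f_v_min0=np.array([0.6]),
                     p_phi_k=np.round(np.arange(0.5, 10.6, 0.5), 10))
    fps = find_fixed_points("F", 0.6, grid=grid)
    stable = [fp for fp in fps if fp.stable]
    assert stable, "expected at least one stable fixed point in the fixture sweep"
    return stable
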