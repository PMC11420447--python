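import numpy as np
import pytest

from leuplat.lattice import GridSpec, NeighborhoodSpec
from leuplat.ndj import IntegrationConfig, NDJParams, simulate_ndj


@pytest.fixture(scope="session")
def grid5():
    return GridSpec(5, 5)


@pytest.fixture(scope="session")
def grid8():
    return GridSpec(8, 8)


@pytest.fixture(scope="session")
def grid12():
    return GridSpec(12, 12)


@pytest.fixture(scope="session")
def grid24():
    return GridSpec(24, 24)


@pytest.fixture(scope="session")
def moore1():
    return NeighborhoodSpec(radius=1, include_focal=False)


@pytest.fixture(scope="session")
def converged_induction_run(grid12):
    """One fully converged Jagged-dominated (lateral-induction) run, shared
    by the quasi-steady-state and diagnostics tests."""
    params = NDJParams(D0=600.0, J0=1200.0)
    cfg = IntegrationConfig(n_steps=30000, seed=7, record_every=300)
    traj = simulate_ndj(None, params, cfg, grid12)
    assert traj.converged_at is not None
    return params, traj


def brute_neighbor_values(field, i, j, radius, include_focal):
    """Reference Moore-neighborhood sample by explicit modular enumeration."""
    rows, cols = field.shape
    vals = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if not include_focal and di == 0 and dj == 0:
                continue
            vals.append(field[(i + di) % rows, (j + dj) % cols])
    return np.array(vals)
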