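"""Shared fixtures: the expensive forward solves are session-scoped so the
end-to-end pipeline (phantom -> solve -> inversion) is computed once and
reused by the unit and acceptance tests."""

import numpy as np
import pytest

from mnpmap.phantom import build_phantom_2d, build_phantom_3d
from mnpmap.solver import (
    SolverConfig,
    calibrate_force_for_peak_strain,
    kelvin_boundary_values,
    solve_static,
)

DOUBLE_INCLUSIONS = [((5.0, 3.75), 10.0, 1.0), ((5.0, 6.25), 5.0, 1.0)]


@pytest.fixture(scope="session")
def fig5a():
    """Single 10 mm inclusion, 10x10 cm, calibrated to 0.1% peak strain."""
    ph = build_phantom_2d(grid_n=201)
    f_cal = calibrate_force_for_peak_strain(ph, 1e-3)
    ph = ph.with_force_density(f_cal)
    field = solve_static(ph)
    return {"phantom": ph, "field": field, "force_density": f_cal}


@pytest.fixture(scope="session")
def double_fine():
    """10 mm + 5 mm inclusions at h = 0.25 mm (both >= 20 voxels across)."""
    ph = build_phantom_2d(grid_n=401, inclusions=DOUBLE_INCLUSIONS).with_force_density(1000.0)
    field = solve_static(ph)
    return {"phantom": ph, "field": field, "force_density": 1000.0}


@pytest.fixture(scope="session")
def kelvin_verification():
    """3D solve of a 10 mm loaded sphere deep in a 10 cm cube, with the
    analytic infinite-medium ball solution imposed on the boundary."""
    ph = build_phantom_3d(
        size_cm=(10.0, 10.0, 10.0), inclusion_D_mm=10.0, grid_n=(61, 61, 61),
        force_density=1000.0,
    )
    bv = kelvin_boundary_values(ph)
    field = solve_static(ph, SolverConfig(boundary_condition="prescribed"), boundary_values=bv)
    center = tuple(n // 2 for n in ph.grid_shape)
    return {"phantom": ph, "field": field, "center_index": center}


@pytest.fixture()
def rng():
    return np.random.default_rng(20121103)
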