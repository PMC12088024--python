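"""Shared fixtures: coarse verification geometries and solved flows.

Session-scoped fixtures keep the expensive pieces (meshing, saddle-point
factorization) to one run per test session; all sizes here are chosen for
speed, the quantitative tolerances that depend on resolution live in the
acceptance tests with their own finer meshes.
"""

import numpy as np
import pytest

from archflow.mesh import structured_tube_mesh
from archflow.solver import (BoundarySpec, FluidProperties, PressureWaveform,
                             steady_solve)

R_TUBE = 0.05   # mm
L_TUBE = 1.0    # mm
DP = 10.0       # Pa


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def poiseuille_bcs():
    return BoundarySpec(pressures={
        "inlet": PressureWaveform.constant(DP),
        "outlet": PressureWaveform.constant(0.0),
    })


@pytest.fixture(scope="session")
def tube_mesh_coarse():
    return structured_tube_mesh(R_TUBE, L_TUBE, h=R_TUBE / 3,
                                axial_h=L_TUBE / 8)


@pytest.fixture(scope="session")
def poiseuille_coarse(tube_mesh_coarse, fluid, poiseuille_bcs):
    return steady_solve(tube_mesh_coarse, fluid, poiseuille_bcs,
                        convection="none")


def poiseuille_axial(verts_m, dp=DP, radius_m=R_TUBE * 1e-3,
                     length_m=L_TUBE * 1e-3, mu=3.71e-3):
    r2 = verts_m[:, 0] ** 2 + verts_m[:, 1] ** 2
    return dp * (radius_m ** 2 - np.minimum(r2, radius_m ** 2)) / (
        4 * mu * length_m)
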