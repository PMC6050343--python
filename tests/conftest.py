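"""Shared fixtures: small converged ICP cases reused across test modules."""

import numpy as np
import pytest

from icpkit import (
    DeviceGeometry,
    DriveSpec,
    ElectrokineticSystem,
    FieldState,
    Mesh,
    MembraneSpec,
    build_mesh,
    voltage_continuation,
)
from icpkit.solver import SolverSettings


@pytest.fixture(scope="session")
def small_geometry():
    return DeviceGeometry(channel_length=2.0e-3, membrane_x_center=1.0e-3)


@pytest.fixture(scope="session")
def small_system(small_geometry):
    return ElectrokineticSystem(geometry=small_geometry)


@pytest.fixture(scope="session")
def small_mesh(small_geometry):
    return build_mesh(small_geometry, nx=60, ny=16)


@pytest.fixture(scope="session")
def converged_icp(small_system, small_mesh):
    """Converged steady ICP state on a coarse 2 mm channel (shared)."""
    state, report = voltage_continuation(small_system, small_mesh, SolverSettings())
    assert report.converged
    return state, report


def make_state(mesh, system, c_plus=None, c_minus=None, phi=None, ux=None, uy=None, P=None):
    """Convenience constructor for synthetic field states."""
    ny, nx = mesh.ny, mesh.nx
    full = lambda arr, shape, fill: (  # noqa: E731
        np.full(shape, fill) if arr is None else np.asarray(arr, float).reshape(shape)
    )
    return FieldState(
        C_plus=full(c_plus, (ny, nx), system.electrolyte.c0),
        C_minus=full(c_minus, (ny, nx), system.electrolyte.c0),
        phi=full(phi, (ny, nx), 0.0),
        ux=full(ux, (ny, nx + 1), 0.0),
        uy=full(uy, (ny + 1, nx), 0.0),
        P=full(P, (ny, nx), 0.0),
        mesh=mesh,
        system=system,
    )


@pytest.fixture()
def no_membrane_case():
    """Short straight channel with no membrane cells and zero drive."""
    mesh = Mesh.from_extents(100e-6, 17e-6, 20, 8)
    geometry = DeviceGeometry(
        channel_length=100e-6, membrane_length=10e-6, membrane_x_center=50e-6
    )
    system = ElectrokineticSystem(geometry=geometry, drive=DriveSpec(axial_field=0.0))
    return mesh, system
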