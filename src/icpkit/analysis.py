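"""Post-processing of converged electrokinetic states.

Extracts the observables that characterize ion concentration
polarization: concentration profiles along a horizontal line (default:
the membrane surface height), depletion/enrichment metrics with the
linearity of the diffusion-limited anodic profile, the ionic current
through vertical cross-sections, and recirculation vortices of the
flow field via the discrete streamfunction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._discretize import Discretization, TransportParams, species_face_fluxes
from .geometry import Mesh
from .solver import FieldState
from .system import nondimensionalize


@dataclass(frozen=True)
class Profile:
    """Ion concentrations sampled along a horizontal line."""

    x: np.ndarray
    C_plus: np.ndarray
    C_minus: np.ndarray
    y: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("profile x positions must be strictly increasing")


@dataclass(frozen=True)
class DepletionReport:
    """Depletion/enrichment metrics of a concentration profile.

    ``r_squared_anodic`` measures the linearity of the quasi-steady
    diffusion profile between the inlet and the depletion-zone edge
    (the point where the concentration first comes within 5% of its
    anodic minimum, measured relative to the bulk-minimum span).
    """

    c_min_anodic: float
    depletion_factor: float
    c_max_cathodic: float
    enrichment_factor: float
    r_squared_anodic: float
    x_min: float
    x_edge: float = 0.0


def extract_profile(state: FieldState, mesh: Mesh | None = None, y: float | None = None) -> Profile:
    """Sample C+ and C- along the horizontal line at height ``y``.

    Column-wise linear interpolation between cell centres, restricted to
    fluid cells: under the membrane the line at the interface height
    samples the fluid side, not the membrane interior.  Defaults to the
    membrane surface height H - t_m.
    """
    mesh = mesh or state.mesh
    if y is None:
        if mesh.geometry is None:
            raise ValueError("no geometry attached; pass y explicitly")
        y = mesh.geometry.interface_y
    H = mesh.y_faces[-1]
    if not (mesh.y_faces[0] <= y <= H):
        raise ValueError(f"y={y:g} outside the channel [0, {H:g}]")
    yc = mesh.yc
    cp_out = np.empty(mesh.nx)
    cm_out = np.empty(mesh.nx)
    for i in range(mesh.nx):
        fluid = ~mesh.membrane_mask[:, i]
        yf = yc[fluid]
        y_eff = float(np.clip(y, yf[0], yf[-1]))
        cp_out[i] = np.interp(y_eff, yf, state.C_plus[fluid, i])
        cm_out[i] = np.interp(y_eff, yf, state.C_minus[fluid, i])
    return Profile(x=mesh.xc.copy(), C_plus=cp_out, C_minus=cm_out, y=y)


def depletion_metrics(
    profile: Profile,
    c0: float,
    membrane_extent: tuple[float, float],
) -> DepletionReport:
    """Depletion/enrichment factors and anodic-profile linearity.

    The anodic (inlet) side is x below the membrane extent, the cathodic
    side above it.  R^2 is for the least-squares line over the segment
    from the inlet to the depletion-zone edge; for a constant profile it
    is reported as 1.0 by convention.
    """
    x_lo, x_hi = membrane_extent
    anodic = profile.x < x_lo
    cathodic = profile.x > x_hi
    if not anodic.any() or not cathodic.any():
        raise ValueError("profile must span both sides of the membrane")
    c_an = profile.C_plus[anodic]
    x_an = profile.x[anodic]
    i_min = int(np.argmin(c_an))
    c_min = float(c_an[i_min])
    x_min = float(x_an[i_min])
    c_max = float(profile.C_plus[cathodic].max())
    # depletion-zone edge: first point whose concentration is within 5%
    # (of the bulk-to-minimum span) of the minimum
    span = c_an[0] - c_min
    if span > 0.0:
        below = np.nonzero(c_an <= c_min + 0.05 * span)[0]
        i_edge = int(below[0]) if len(below) else i_min
    else:
        i_edge = i_min
    x_edge = float(x_an[i_edge])
    seg = slice(0, max(i_edge, 1) + 1)
    xs, ys = x_an[seg], c_an[seg]
    if len(xs) < 3 or np.ptp(ys) == 0.0:
        r2 = 1.0
    else:
        r2 = float(stats.linregress(xs, ys).rvalue ** 2)
    return DepletionReport(
        c_min_anodic=c_min,
        depletion_factor=c0 / c_min if c_min > 0 else np.inf,
        c_max_cathodic=c_max,
        enrichment_factor=c_max / c0,
        r_squared_anodic=r2,
        x_min=x_min,
        x_edge=x_edge,
    )


def compute_current(state: FieldState, mesh: Mesh | None = None, x_section: float | None = None) -> float:
    """Ionic current per unit channel depth (A/m) through the vertical
    cross-section nearest ``x_section``.

    Integrates F(z+ J+ + z- J-) over the section using the same
    Scharfetter-Gummel/upwind face fluxes as the solver, membrane cells
    included (the membrane carries the cation current).  In a converged
    steady state this is independent of the section to discretization
    accuracy.
    """
    mesh = mesh or state.mesh
    sys_ = state.system
    if x_section is None:
        x_section = 0.5 * (mesh.x_faces[0] + mesh.x_faces[-1])
    if not (mesh.x_faces[0] < x_section < mesh.x_faces[-1]):
        raise ValueError("x_section outside the domain interior")
    scaled = nondimensionalize(
        sys_.constants, sys_.electrolyte, sys_.geometry, sys_.drive,
        membrane=sys_.membrane, walls=sys_.walls,
    )
    disc = Discretization(mesh, scaled, cation_only=sys_.membrane.cation_only,
                          membrane_d_factor=sys_.membrane.diffusivity_factor)
    c_don = sys_.membrane.donnan_anion_concentration(sys_.electrolyte.c0)
    par = TransportParams.from_scaled(
        scaled, sys_.electrolyte.z_plus, sys_.electrolyte.z_minus,
        c_donnan=c_don / sys_.electrolyte.c0,
    )
    cp = scaled.scale_concentration(state.C_plus).ravel()
    cm = scaled.scale_concentration(state.C_minus).ravel()
    phi = scaled.scale_potential(state.phi).ravel()
    ux = scaled.scale_velocity(state.ux)
    uy = scaled.scale_velocity(state.uy)
    # interior face column closest to the requested section
    i_face = int(np.argmin(np.abs(mesh.x_faces[1:-1] - x_section)))  # face index i_face+1
    sel = disc.fx_i == i_face
    jp = species_face_fluxes(disc, par, par.z_plus, par.d_plus, cp, phi, ux, uy, "x")[sel]
    jm = species_face_fluxes(disc, par, par.z_minus, par.d_minus, cm, phi, ux, uy, "x")[sel]
    jm = jm * disc.fx_anion[sel]  # cation-only membrane blocks anion flux
    area = disc.fx_area[sel]
    flux_scale = scaled.diffusivity * scaled.concentration  # J_SI * L = J~ * D_ref c0
    current = sys_.constants.F * np.sum((par.z_plus * jp + par.z_minus * jm) * area) * flux_scale
    return float(current)


@dataclass(frozen=True)
class VortexReport:
    """Recirculation cells found in a velocity field."""

    count: int
    centroids: list[tuple[float, float]]
    peak_speeds: list[float]


def streamfunction(state: FieldState, mesh: Mesh | None = None) -> np.ndarray:
    """Discrete streamfunction at mesh nodes, psi=0 on the bottom wall.

    psi[j+1,i] - psi[j,i] = ux[j,i] * dy[j]; exact for the MAC field.
    """
    mesh = mesh or state.mesh
    psi = np.zeros((mesh.ny + 1, mesh.nx + 1))
    psi[1:, :] = np.cumsum(state.ux * mesh.dy[:, None], axis=0)
    return psi


def detect_vortices(
    state: FieldState,
    mesh: Mesh | None = None,
    divergence_tol: float = 1.0e-6,
    prominence: float = 1.0e-9,
) -> VortexReport:
    """Count recirculation cells as interior extrema of the streamfunction.

    A strict interior local extremum of psi is surrounded by closed
    streamlines, i.e. a vortex.  Raises if the velocity field is not
    discretely divergence-free (the streamfunction would be ill-defined).
    """
    mesh = mesh or state.mesh
    div = (
        (state.ux[:, 1:] - state.ux[:, :-1]) * mesh.dy[:, None]
        + (state.uy[1:, :] - state.uy[:-1, :]) * mesh.dx[None, :]
    ) / np.outer(mesh.dy, mesh.dx)
    u_scale = max(np.abs(state.ux).max(), np.abs(state.uy).max(), 1.0e-300)
    h_min = min(mesh.dx.min(), mesh.dy.min())
    if np.abs(div).max() > divergence_tol * u_scale / h_min:
        raise ValueError("velocity field is not divergence-free; cannot build streamfunction")
    psi = streamfunction(state, mesh)
    rng = np.ptp(psi)
    if rng == 0.0:
        return VortexReport(count=0, centroids=[], peak_speeds=[])
    centroids: list[tuple[float, float]] = []
    peaks: list[float] = []
    speed = state.speed
    inner = psi[1:-1, 1:-1]
    neighbours = [
        psi[1 + dj:psi.shape[0] - 1 + dj, 1 + di:psi.shape[1] - 1 + di]
        for dj in (-1, 0, 1) for di in (-1, 0, 1) if (dj, di) != (0, 0)
    ]
    stack = np.stack(neighbours)
    is_max = np.all(inner > stack + prominence * rng, axis=0)
    is_min = np.all(inner < stack - prominence * rng, axis=0)
    for jj, ii in zip(*np.nonzero(is_max | is_min)):
        j, i = jj + 1, ii + 1
        centroids.append((float(mesh.x_faces[i]), float(mesh.y_faces[j])))
        j_c = min(j, mesh.ny - 1)
        i_c = min(i, mesh.nx - 1)
        peaks.append(float(speed[max(j_c - 1, 0):j_c + 1, max(i_c - 1, 0):i_c + 1].max()))
    return VortexReport(count=len(centroids), centroids=centroids, peak_speeds=peaks)
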