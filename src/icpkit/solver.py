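"""Steady Poisson-Nernst-Planck-Stokes solver.

The coupled system (ion conservation with Scharfetter-Gummel
drift-diffusion fluxes and upwinded advection, Poisson with membrane
fixed charge, creeping-flow momentum with the electric body force, and
continuity) is solved to steady state by alternating

1. a damped Newton iteration on the coupled (c+, c-, phi) block with an
   analytic sparse Jacobian at frozen velocity, and
2. an exact sparse linear solve of the Stokes block at frozen charge
   density and potential,

until the full residual over all unknowns is converged.  Robustness at
the strongly nonlinear operating point (hundreds of thermal voltages
across the domain) comes from voltage continuation: the applied field
is ramped through intermediate values, each solve warm-starting from
the previous converged state.

The physical Debye length at 10 mM (~3 nm) cannot be resolved on a
17 um channel; the Poisson coefficient uses a numerically inflated
Debye length (default: inflated to span two of the smallest cells), the
standard device-scale rescaling for this class of simulation.  The
electroosmotic slip condition always uses the *physical* permittivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse.linalg as spla

from ._discretize import Discretization, TransportParams, pnp_residual
from .geometry import Mesh
from .stokes import StokesOperator
from .system import ElectrokineticSystem, ScaledSystem, nondimensionalize

logger = logging.getLogger(__name__)


@dataclass
class FieldState:
    """Discrete solution fields in SI units on a structured mesh.

    ``C_plus``/``C_minus``/``phi``/``P`` are cell-centred (ny, nx);
    ``ux`` (ny, nx+1) and ``uy`` (ny+1, nx) live on MAC faces.
    """

    C_plus: np.ndarray
    C_minus: np.ndarray
    phi: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    P: np.ndarray
    mesh: Mesh
    system: ElectrokineticSystem

    @property
    def rho_e(self) -> np.ndarray:
        """Space charge density F(z+ C+ + z- C-) + membrane fixed charge, C/m^3."""
        e = self.system.electrolyte
        F = self.system.constants.F
        rho = F * (e.z_plus * self.C_plus + e.z_minus * self.C_minus)
        rho = rho + F * self.system.membrane.fixed_charge_concentration * self.mesh.membrane_mask
        return rho

    @property
    def speed(self) -> np.ndarray:
        """Cell-centred velocity magnitude, m/s."""
        uxc = 0.5 * (self.ux[:, :-1] + self.ux[:, 1:])
        uyc = 0.5 * (self.uy[:-1, :] + self.uy[1:, :])
        return np.hypot(uxc, uyc)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the nonlinear solve."""

    newton_tolerance: float = 1.0e-9     # rms of the scaled PNP residual
    max_newton_iters: int = 40
    linear_solver: str = "direct"        # "direct" (sparse LU) or "gmres" (+ILU)
    linear_tolerance: float = 1.0e-10
    continuation: tuple[float, ...] | None = None  # fractions of the target field
    damping_min: float = 1.0 / 1024.0
    debye_scale: float | None = None     # None -> inflate lambda_D to 2 min cells
    include_flow: bool = True
    max_outer_iters: int = 60
    outer_tolerance: float = 1.0e-8      # relative velocity change between outer iters
    under_relax: float = 0.7
    concentration_floor: float = 1.0e-12  # scaled positivity guard
    flow_bc: str = "zero_net_flow"       # or "open" (both reservoirs at P=0)

    def __post_init__(self) -> None:
        if not (0.0 < self.newton_tolerance < 1.0):
            raise ValueError("newton_tolerance must lie in (0, 1)")
        if not (0.0 < self.linear_tolerance < 1.0):
            raise ValueError("linear_tolerance must lie in (0, 1)")
        if self.continuation is not None:
            fr = np.asarray(self.continuation, float)
            if len(fr) == 0 or np.any(np.diff(fr) <= 0) or fr[0] <= 0:
                raise ValueError("continuation fractions must be strictly increasing and positive")


@dataclass
class SolveReport:
    """Convergence diagnostics of one solve."""

    converged: bool
    steps: list[dict] = field(default_factory=list)
    final_residual: float = np.inf
    message: str = ""
    summary: dict = field(default_factory=dict)


class Workspace:
    """Cached discretization, scaling and Stokes factorization for one
    (system, mesh, settings) triple.  The scaling (velocity reference,
    kappa, Peclet) is fixed at the *target* drive so that continuation
    steps can share one Stokes factorization and one state scaling."""

    def __init__(self, system: ElectrokineticSystem, mesh: Mesh, settings: SolverSettings):
        self.system = system
        self.mesh = mesh
        self.settings = settings
        scale0 = nondimensionalize(
            system.constants, system.electrolyte, system.geometry, system.drive,
            membrane=system.membrane, walls=system.walls,
        )
        if settings.debye_scale is not None:
            dscale = settings.debye_scale
        else:
            h_min = min(mesh.dx.min(), mesh.dy.min())
            lam_phys = scale0.lambda_tilde_physical * scale0.length
            dscale = max(1.0, 2.0 * h_min / lam_phys)
        self.scaled: ScaledSystem = nondimensionalize(
            system.constants, system.electrolyte, system.geometry, system.drive,
            membrane=system.membrane, walls=system.walls, debye_scale=dscale,
        )
        self.disc = Discretization(mesh, self.scaled, cation_only=system.membrane.cation_only,
                                   membrane_d_factor=system.membrane.diffusivity_factor)
        c_don = system.membrane.donnan_anion_concentration(system.electrolyte.c0)
        self.params = TransportParams.from_scaled(
            self.scaled, system.electrolyte.z_plus, system.electrolyte.z_minus,
            c_donnan=c_don / system.electrolyte.c0,
        )
        self.stokes = StokesOperator(self.disc) if settings.include_flow else None

    # -- state conversions ------------------------------------------------
    def initial_guess(self, delta_v: float):
        disc = self.disc
        cp = np.ones(disc.N)
        cm = np.ones(disc.N)
        if disc.cation_only and disc.mem.any():
            cm[disc.mem] = self.params.c_donnan
            cp[disc.mem] = self.params.c_donnan - self.params.n_fixed
        x0 = disc.x_faces[0]
        phi = delta_v * (1.0 - (np.tile(disc.xc, disc.ny) - x0) / disc.length_x)
        ux = np.zeros((disc.ny, disc.nx + 1))
        uy = np.zeros((disc.ny + 1, disc.nx))
        P = np.zeros(disc.N)
        return cp, cm, phi, ux, uy, P

    def to_state(self, cp, cm, phi, ux, uy, P) -> FieldState:
        s = self.scaled
        ny, nx = self.disc.ny, self.disc.nx
        return FieldState(
            C_plus=s.unscale_concentration(cp).reshape(ny, nx),
            C_minus=s.unscale_concentration(cm).reshape(ny, nx),
            phi=s.unscale_potential(phi).reshape(ny, nx),
            ux=s.unscale_velocity(ux),
            uy=s.unscale_velocity(uy),
            P=s.unscale_pressure(P).reshape(ny, nx),
            mesh=self.mesh,
            system=self.system,
        )

    def from_state(self, state: FieldState):
        s = self.scaled
        return (
            s.scale_concentration(state.C_plus).ravel(),
            s.scale_concentration(state.C_minus).ravel(),
            s.scale_potential(state.phi).ravel(),
            s.scale_velocity(state.ux).copy(),
            s.scale_velocity(state.uy).copy(),
            s.scale_pressure(state.P).ravel(),
        )

    # -- linear solver -----------------------------------------------------
    def _solve_linear(self, J, rhs):
        if self.settings.linear_solver == "gmres":
            try:
                ilu = spla.spilu(J.tocsc(), drop_tol=1.0e-5, fill_factor=30)
                M = spla.LinearOperator(J.shape, ilu.solve)
                sol, info = spla.gmres(
                    J, rhs, M=M, rtol=self.settings.linear_tolerance,
                    restart=100, maxiter=200,
                )
                if info == 0:
                    return sol
                logger.warning("GMRES stagnated (info=%s); falling back to direct solve", info)
            except RuntimeError as exc:
                logger.warning("ILU factorization failed (%s); falling back to direct solve", exc)
        return spla.splu(J.tocsc()).solve(rhs)

    # -- PNP Newton --------------------------------------------------------
    def newton_pnp(self, cp, cm, phi, ux, uy, delta_v: float):
        """Damped Newton on the (c+, c-, phi) block at frozen velocity."""
        st = self.settings
        par = replace(self.params, delta_v=delta_v)
        N = self.disc.N
        x = np.concatenate([cp, cm, phi])

        def rms(r):
            return float(np.linalg.norm(r) / np.sqrt(len(r)))

        R, _ = pnp_residual(self.disc, par, x[:N], x[N:2 * N], x[2 * N:], ux, uy)
        res = rms(R)
        iters = 0
        bad_steps = 0
        while res > st.newton_tolerance and iters < st.max_newton_iters:
            R, J = pnp_residual(self.disc, par, x[:N], x[N:2 * N], x[2 * N:], ux, uy,
                                want_jacobian=True)
            try:
                delta = self._solve_linear(J, -R)
            except RuntimeError as exc:
                return x, res, iters, False, f"linear solve failed: {exc}"
            # positivity guard on concentrations
            conc = x[:2 * N]
            dconc = delta[:2 * N]
            neg = dconc < 0.0
            alpha_max = 1.0
            if np.any(neg):
                alpha_max = min(1.0, float(np.min(
                    0.99 * (conc[neg] - st.concentration_floor) / (-dconc[neg])
                )))
                alpha_max = max(alpha_max, st.damping_min)
            alpha = alpha_max
            accepted = False
            while alpha >= st.damping_min:
                x_try = x + alpha * delta
                R_try, _ = pnp_residual(self.disc, par, x_try[:N], x_try[N:2 * N],
                                        x_try[2 * N:], ux, uy)
                res_try = rms(R_try)
                if res_try < (1.0 - 1.0e-4 * alpha) * res:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                bad_steps += 1
                if bad_steps >= 3:
                    return x, res, iters, False, "Newton stalled (no descent direction)"
                x_try = x + st.damping_min * delta
                R_try, _ = pnp_residual(self.disc, par, x_try[:N], x_try[N:2 * N],
                                        x_try[2 * N:], ux, uy)
                res_try = rms(R_try)
            else:
                bad_steps = 0
            x, res = x_try, res_try
            iters += 1
        ok = res <= st.newton_tolerance
        return x, res, iters, ok, "" if ok else "max Newton iterations reached"

    # -- one steady solve at a given drive ---------------------------------
    def solve_at(self, delta_v: float, warm=None):
        st = self.settings
        if warm is None:
            cp, cm, phi, ux, uy, P = self.initial_guess(delta_v)
        else:
            cp, cm, phi, ux, uy, P = warm
        par = replace(self.params, delta_v=delta_v)
        info: dict = {"delta_v": delta_v, "newton_iters": [], "outer_iters": 0}
        converged = False
        message = ""
        for outer in range(st.max_outer_iters if st.include_flow else 1):
            x, res, iters, ok, message = self.newton_pnp(cp, cm, phi, ux, uy, delta_v)
            N = self.disc.N
            cp, cm, phi = x[:N], x[N:2 * N], x[2 * N:]
            info["newton_iters"].append(iters)
            info["outer_iters"] = outer + 1
            if not ok:
                break
            if not st.include_flow:
                converged = True
                break
            ux_new, uy_new, P_new = self.stokes.solve(
                par, cp, cm, phi, self.scaled.kappa,
                self.scaled.slip_coeff_bottom, self.scaled.slip_coeff_top,
                flow_bc=st.flow_bc,
            )
            w = st.under_relax
            ux_next = w * ux_new + (1.0 - w) * ux
            uy_next = w * uy_new + (1.0 - w) * uy
            scale_u = max(np.abs(ux_next).max(), np.abs(uy_next).max(), 1.0e-30)
            du = max(np.abs(ux_next - ux).max(), np.abs(uy_next - uy).max()) / scale_u
            ux, uy, P = ux_next, uy_next, P_new.ravel()
            if du < st.outer_tolerance:
                converged = True
                break
        else:
            message = "outer PNP/Stokes iteration did not converge"
        info["pnp_residual"] = res
        info["converged"] = converged
        return (cp, cm, phi, ux, uy, P), res, converged, message, info


def _make_workspace(system, mesh, settings):
    return Workspace(system, mesh, settings or SolverSettings())


def assemble_residual(
    state: FieldState,
    system: ElectrokineticSystem | None = None,
    mesh: Mesh | None = None,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Full scaled residual vector of a state: [cation, anion, Poisson,
    x-momentum, y-momentum, continuity].

    Zero only at an exact discrete steady state.  NaN or negative
    concentrations are flagged via logging but the residual is still
    returned (it is what a line search needs).
    """
    system = system or state.system
    mesh = mesh or state.mesh
    ws = _make_workspace(system, mesh, settings)
    cp, cm, phi, ux, uy, P = ws.from_state(state)
    if np.any(~np.isfinite(cp)) or np.any(~np.isfinite(cm)) or np.any(cp < 0) or np.any(cm < 0):
        logger.warning("state contains NaN or negative concentrations")
    R_pnp, _ = pnp_residual(ws.disc, ws.params, cp, cm, phi, ux, uy)
    if ws.stokes is not None:
        R_st = ws.stokes.residual(
            ws.params, ux, uy, P, cp, cm, phi, ws.scaled.kappa,
            ws.scaled.slip_coeff_bottom, ws.scaled.slip_coeff_top,
            flow_bc=settings.flow_bc if settings else SolverSettings().flow_bc,
        )
    else:
        R_st = np.zeros(0)
    return np.concatenate([R_pnp, R_st])


def newton_solve(
    system: ElectrokineticSystem,
    mesh: Mesh,
    initial: FieldState | None = None,
    settings: SolverSettings | None = None,
    workspace: Workspace | None = None,
) -> tuple[FieldState, SolveReport]:
    """Solve the steady coupled system at the system's drive.

    Deterministic for identical inputs.  A non-converged run returns the
    last iterate with ``report.converged == False``; it never returns an
    unflagged bad state.
    """
    settings = settings or SolverSettings()
    ws = workspace or Workspace(system, mesh, settings)
    warm = ws.from_state(initial) if initial is not None else None
    sol, res, converged, message, info = ws.solve_at(ws.scaled.delta_v, warm=warm)
    state = ws.to_state(*sol)
    report = SolveReport(
        converged=converged, steps=[info], final_residual=res, message=message,
        summary=_state_summary(state),
    )
    return state, report


def voltage_continuation(
    system: ElectrokineticSystem,
    mesh: Mesh,
    settings: SolverSettings | None = None,
) -> tuple[FieldState, SolveReport]:
    """Ramp the applied field to the target through intermediate steps.

    Each step warm-starts from the previous converged state; a failing
    step is bisected (up to 4 levels) before giving up.  The converged
    answer is a steady state and therefore independent of the path for
    converging cases.
    """
    settings = settings or SolverSettings()
    ws = Workspace(system, mesh, settings)
    target = ws.scaled.delta_v
    if settings.continuation is not None:
        fractions = list(settings.continuation)
    elif target == 0.0:
        fractions = [1.0]
    else:
        fractions = [0.0125, 0.025, 0.05, 0.1, 0.15, 0.22, 0.3, 0.4, 0.5, 0.65, 0.8, 1.0]
    steps = [f * target for f in fractions]

    report = SolveReport(converged=False)
    warm = None
    prev_dv = 0.0
    queue = list(steps)
    failures_allowed = 15
    res = np.inf
    while queue:
        dv = queue[0]
        sol, res, converged, message, info = ws.solve_at(dv, warm=warm)
        if converged:
            warm = sol
            prev_dv = dv
            queue.pop(0)
            report.steps.append(info)
        else:
            failures_allowed -= 1
            if failures_allowed < 0 or dv - prev_dv < 1.0e-6 * max(target, 1.0):
                report.message = f"continuation failed at delta_v={dv:.4g}: {message}"
                report.final_residual = res
                state = ws.to_state(*(warm if warm is not None else sol))
                report.summary = _state_summary(state)
                return state, report
            queue.insert(0, 0.5 * (prev_dv + dv))
            report.steps.append({**info, "bisected": True})
    report.converged = True
    report.final_residual = res
    state = ws.to_state(*warm)
    report.summary = _state_summary(state)
    return state, report


def _state_summary(state: FieldState) -> dict:
    return {
        "c_plus_min_mM": float(state.C_plus.min()),
        "c_plus_max_mM": float(state.C_plus.max()),
        "max_speed_um_per_s": float(state.speed.max() * 1e6),
        "phi_drop_V": float(state.phi.max() - state.phi.min()),
    }
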