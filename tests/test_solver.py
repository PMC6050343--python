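"""PNP-Stokes solver correctness: residuals, Jacobian, oracles, invariants."""

import numpy as np
import pytest

from icpkit import (
    DeviceGeometry,
    DriveSpec,
    ElectrokineticSystem,
    MembraneSpec,
    Mesh,
    WallSpec,
    assemble_residual,
    compute_current,
    newton_solve,
    voltage_continuation,
)
from icpkit._discretize import Discretization, TransportParams, bernoulli, dbernoulli, pnp_residual
from icpkit.solver import SolverSettings, Workspace

from conftest import make_state


class TestBernoulli:
    def test_limits_and_symmetry(self):
        x = np.array([-700.0, -10.0, -1e-10, 0.0, 1e-10, 10.0, 700.0])
        b = bernoulli(x)
        assert b[3] == 1.0
        assert np.all(np.isfinite(b))
        # B(-x) - B(x) = x
        xs = np.linspace(-30, 30, 101)
        np.testing.assert_allclose(bernoulli(-xs) - bernoulli(xs), xs, atol=1e-12)

    def test_derivative_matches_finite_difference(self):
        xs = np.array([-200.0, -5.0, -0.3, 2e-7, 0.7, 5.0, 200.0])
        eps = 1e-6
        fd = (bernoulli(xs + eps) - bernoulli(xs - eps)) / (2 * eps)
        np.testing.assert_allclose(dbernoulli(xs), fd, rtol=1e-5, atol=1e-8)


class TestResidual:
    def test_equilibrium_state_residual_zero(self, no_membrane_case):
        """Uniform concentrations, zero potential and no drive are an
        exact steady state."""
        mesh, system = no_membrane_case
        state = make_state(mesh, system)
        R = assemble_residual(state)
        assert np.abs(R).max() == pytest.approx(0.0, abs=1e-13)

    def test_ohmic_interior_residual_zero(self, no_membrane_case):
        """Linear potential + uniform concentration + zero velocity solve
        the interior NP and Poisson equations exactly."""
        mesh, system = no_membrane_case
        system = system.with_drive(3.6e3)
        dv = 3.6e3 * 100e-6
        phi = dv * (1.0 - mesh.xc / 100e-6)
        state = make_state(mesh, system, phi=np.tile(phi, (mesh.ny, 1)))
        ws = Workspace(system, mesh, SolverSettings(include_flow=False))
        cp, cm, p, ux, uy, _ = ws.from_state(state)
        R, _ = pnp_residual(ws.disc, ws.params, cp, cm, p, ux, uy)
        N = ws.disc.N
        interior = np.ones(N, bool)
        interior[ws.disc.bw_k] = interior[ws.disc.be_k] = False
        mask = np.concatenate([interior, interior, interior])
        assert np.abs(R[mask]).max() < 1e-12

    def test_jacobian_consistency_second_order(self):
        """R(x + d*v) - R(x) - d*J v vanishes as O(d^2)."""
        from icpkit import build_mesh

        geometry = DeviceGeometry(channel_length=200e-6, membrane_length=50e-6,
                                  membrane_x_center=100e-6)
        mesh = build_mesh(geometry, nx=12, ny=8)
        system = ElectrokineticSystem(geometry=geometry, drive=DriveSpec(axial_field=1.0e3))
        ws = Workspace(system, mesh, SolverSettings())
        rng = np.random.default_rng(3)
        N = ws.disc.N
        cp = 1.0 + 0.3 * rng.random(N)
        cm = 1.0 + 0.3 * rng.random(N)
        cm[ws.disc.mem] = ws.params.c_donnan
        phi = rng.normal(0.0, 0.5, N)
        ux = 0.1 * rng.normal(size=(ws.disc.ny, ws.disc.nx + 1))
        uy = 0.1 * rng.normal(size=(ws.disc.ny + 1, ws.disc.nx))
        x0 = np.concatenate([cp, cm, phi])
        R0, J = pnp_residual(ws.disc, ws.params, cp, cm, phi, ux, uy, want_jacobian=True)
        v = rng.normal(size=3 * N)
        v /= np.linalg.norm(v)
        errs = []
        for delta in (1e-3, 5e-4, 2.5e-4):
            x1 = x0 + delta * v
            R1, _ = pnp_residual(ws.disc, ws.params, x1[:N], x1[N:2 * N], x1[2 * N:], ux, uy)
            errs.append(np.linalg.norm(R1 - R0 - delta * (J @ v)))
        errs = np.array(errs)
        # halving the step should quarter the remainder
        assert errs[1] / errs[0] == pytest.approx(0.25, rel=0.25)
        assert errs[2] / errs[1] == pytest.approx(0.25, rel=0.25)


class TestNewton:
    def test_equilibrium_start_converges_immediately(self, no_membrane_case):
        mesh, system = no_membrane_case
        settings = SolverSettings(include_flow=False)
        state, report = newton_solve(system, mesh, settings=settings)
        assert report.converged
        assert report.steps[0]["newton_iters"][0] <= 1

    def test_ohmic_case_linear_potential_uniform_concentration(self, no_membrane_case):
        mesh, system = no_membrane_case
        system = system.with_drive(3.6e3)
        state, report = newton_solve(system, mesh, settings=SolverSettings(include_flow=False))
        assert report.converged
        c0 = system.electrolyte.c0
        assert np.abs(state.C_plus - c0).max() / c0 < 1e-8
        dv = 3.6e3 * 100e-6
        phi_exact = dv * (1.0 - mesh.xc / 100e-6)
        assert np.abs(state.phi - phi_exact).max() / dv < 1e-8

    def test_gmres_linear_solver_matches_direct(self, no_membrane_case):
        mesh, system = no_membrane_case
        system = system.with_drive(2.0e3)
        direct, _ = newton_solve(system, mesh, settings=SolverSettings(include_flow=False))
        gmres, rep = newton_solve(
            system, mesh,
            settings=SolverSettings(include_flow=False, linear_solver="gmres"),
        )
        assert rep.converged
        np.testing.assert_allclose(gmres.phi, direct.phi, atol=1e-8)

    def test_deterministic(self, no_membrane_case):
        mesh, system = no_membrane_case
        system = system.with_drive(2.0e3)
        s1, _ = newton_solve(system, mesh, settings=SolverSettings(include_flow=False))
        s2, _ = newton_solve(system, mesh, settings=SolverSettings(include_flow=False))
        np.testing.assert_array_equal(s1.C_plus, s2.C_plus)
        np.testing.assert_array_equal(s1.phi, s2.phi)


class TestContinuation:
    def test_zero_target_returns_equilibrium(self, no_membrane_case):
        mesh, system = no_membrane_case
        state, report = voltage_continuation(system, mesh, SolverSettings(include_flow=False))
        assert report.converged
        assert np.abs(state.phi).max() < 1e-9
        assert np.abs(state.C_plus - system.electrolyte.c0).max() < 1e-8

    def test_path_independence(self, small_system, small_mesh):
        """Different continuation ladders reach the same steady state."""
        settings_a = SolverSettings(continuation=(0.05, 0.1, 0.2, 0.3, 0.45, 0.6, 0.8, 1.0))
        settings_b = SolverSettings(continuation=(0.1, 0.3, 0.6, 1.0))
        sys_mild = small_system.with_drive(0.9e3)  # mild drive converges on both ladders
        state_a, rep_a = voltage_continuation(sys_mild, small_mesh, settings_a)
        state_b, rep_b = voltage_continuation(sys_mild, small_mesh, settings_b)
        assert rep_a.converged and rep_b.converged
        scale = np.abs(state_a.C_plus).max()
        assert np.abs(state_a.C_plus - state_b.C_plus).max() / scale < 1e-6
        assert np.abs(state_a.ux - state_b.ux).max() <= 1e-6 * max(np.abs(state_a.ux).max(), 1e-30)


class TestConvergedInvariants:
    def test_discrete_divergence_free(self, converged_icp, small_mesh):
        state, _ = converged_icp
        div = (
            (state.ux[:, 1:] - state.ux[:, :-1]) * small_mesh.dy[:, None]
            + (state.uy[1:, :] - state.uy[:-1, :]) * small_mesh.dx[None, :]
        ) / np.outer(small_mesh.dy, small_mesh.dx)
        u_scale = np.abs(state.ux).max() / small_mesh.dy.min()
        assert np.abs(div).max() / u_scale < 1e-10

    def test_current_conserved_across_sections(self, converged_icp):
        state, _ = converged_icp
        currents = [compute_current(state, x_section=x) for x in (0.4e-3, 0.9e-3, 1.1e-3, 1.6e-3)]
        ref = currents[0]
        for i in currents[1:]:
            assert abs(i - ref) / abs(ref) < 1e-3

    def test_anion_permselectivity(self, converged_icp, small_mesh, small_system):
        """Anion flux through the membrane interface is blocked; cation
        flux through the membrane is finite."""
        from icpkit._discretize import species_face_fluxes
        from icpkit.system import nondimensionalize

        state, _ = converged_icp
        sys_ = small_system
        scaled = nondimensionalize(sys_.constants, sys_.electrolyte, sys_.geometry,
                                   sys_.drive, membrane=sys_.membrane, walls=sys_.walls)
        disc = Discretization(small_mesh, scaled, cation_only=True,
                              membrane_d_factor=sys_.membrane.diffusivity_factor)
        par = TransportParams.from_scaled(
            scaled, 1, -1,
            c_donnan=sys_.membrane.donnan_anion_concentration(sys_.electrolyte.c0) / sys_.electrolyte.c0,
        )
        cp = scaled.scale_concentration(state.C_plus).ravel()
        cm = scaled.scale_concentration(state.C_minus).ravel()
        phi = scaled.scale_potential(state.phi).ravel()
        ux = scaled.scale_velocity(state.ux)
        uy = scaled.scale_velocity(state.uy)
        mem_face = ~disc.fx_anion
        jp = species_face_fluxes(disc, par, 1, par.d_plus, cp, phi, ux, uy, "x")
        cation_mem_flux = np.abs(jp[mem_face] * disc.fx_area[mem_face]).sum()
        assert cation_mem_flux > 0.0
        # anion flux through those faces is identically zero by construction
        jm = species_face_fluxes(disc, par, -1, par.d_minus, cm, phi, ux, uy, "x")
        assert np.all((jm * disc.fx_anion)[mem_face] == 0.0)

    def test_mirror_symmetry_of_discretization(self, small_mesh, small_system, converged_icp):
        """Mirroring the fields in x and negating the drive maps a steady
        state onto a steady state of the reversed-bias problem: the PNP
        residual of the mirrored state (evaluated at the negated voltage
        drop) matches the original's."""
        from dataclasses import replace as dc_replace

        state, report = converged_icp
        ws = Workspace(small_system, small_mesh, SolverSettings())
        cp, cm, phi, ux, uy, P = ws.from_state(state)
        dv = ws.scaled.delta_v
        ny, nx = small_mesh.ny, small_mesh.nx
        flip = lambda a: np.ascontiguousarray(a.reshape(ny, nx)[:, ::-1]).ravel()  # noqa: E731
        cp_m, cm_m = flip(cp), flip(cm)
        phi_m = flip(phi) - dv          # reversed bias: inlet at -dv, outlet 0
        ux_m = -ux[:, ::-1]
        uy_m = uy[:, ::-1]
        par_m = dc_replace(ws.params, delta_v=-dv)
        R_orig, _ = pnp_residual(ws.disc, ws.params, cp, cm, phi, ux, uy)
        R_mirror, _ = pnp_residual(ws.disc, par_m, cp_m, cm_m, phi_m, ux_m, uy_m)
        assert np.linalg.norm(R_mirror) == pytest.approx(np.linalg.norm(R_orig), abs=1e-8)


class TestQuasi1DOracle:
    def test_concentration_polarization_closed_form(self):
        """A membrane spanning the full outlet of a quasi-1D channel
        reproduces classical concentration polarization: with the anion
        at zero flux the steady profile is linear with slope set by the
        current, C(x) = c0 - I x / (2 F D+)."""
        L, H = 200e-6, 4e-6
        n_mem = 10
        mesh = Mesh.from_extents(L, H, 100, 2, membrane_box=(L - n_mem * 2e-6, L, 0.0, H))
        geometry = DeviceGeometry(channel_length=L, channel_height=H,
                                  membrane_length=20e-6, membrane_thickness=2e-6,
                                  membrane_x_center=L / 2)
        vt = 8.314462 * 298.15 / 96485.332
        drive = DriveSpec(axial_field=4.0 * vt / L)  # ~4 thermal voltages in total
        system = ElectrokineticSystem(
            geometry=geometry,
            membrane=MembraneSpec(fixed_charge_concentration=-100.0, diffusivity_factor=1.0),
            walls=WallSpec(zeta_bottom=-1e-9, zeta_top=-1e-9),
            drive=drive,
        )
        settings = SolverSettings(include_flow=False, debye_scale=300.0)
        state, report = voltage_continuation(system, mesh, settings)
        assert report.converged
        c0 = system.electrolyte.c0
        F, Dp = system.constants.F, system.electrolyte.D_plus
        current = compute_current(state, x_section=0.25 * L)
        i_density = current / H  # A/m^2
        electrolyte = mesh.xc < (L - n_mem * 2e-6) - 8 * 300.0 * system.debye_length
        c_line = state.C_plus[0, electrolyte]
        c_pred = c0 - i_density * mesh.xc[electrolyte] / (2.0 * F * Dp)
        l2 = np.linalg.norm(c_line - c_pred) / np.linalg.norm(c_pred)
        assert l2 < 0.01
        # underlimiting: interface concentration depleted but finite
        assert 0.0 < state.C_plus[0, electrolyte][-1] < c0

    def test_depletion_deepens_with_drive(self):
        """Depletion factor grows monotonically with the applied field in
        the underlimiting regime."""
        L, H = 200e-6, 4e-6
        mesh = Mesh.from_extents(L, H, 80, 2, membrane_box=(L - 20e-6, L, 0.0, H))
        geometry = DeviceGeometry(channel_length=L, channel_height=H,
                                  membrane_length=20e-6, membrane_thickness=2e-6,
                                  membrane_x_center=L / 2)
        vt = 8.314462 * 298.15 / 96485.332
        mins = []
        for n_vt in (1.0, 3.0, 6.0):
            system = ElectrokineticSystem(
                geometry=geometry,
                membrane=MembraneSpec(diffusivity_factor=1.0),
                walls=WallSpec(zeta_bottom=-1e-9, zeta_top=-1e-9),
                drive=DriveSpec(axial_field=n_vt * vt / L),
            )
            state, report = voltage_continuation(
                system, mesh, SolverSettings(include_flow=False, debye_scale=1000.0)
            )
            assert report.converged
            mins.append(state.C_plus[0, mesh.xc < L - 30e-6].min())
        assert mins[0] > mins[1] > mins[2]
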