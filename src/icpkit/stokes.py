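"""Steady creeping-flow (Stokes) solver on a staggered MAC grid.

Scaled momentum balance: 0 = -grad(P) + lap(u) - kappa * rho_e * grad(phi),
with div(u) = 0, where kappa = F c0 V_T H / (mu u_ref) couples the
electric body force and rho_e = z+ c+ + z- c- + n_fixed is the scaled
space charge.  Inertia is dropped (Re << 1 at channel scale).

Boundary conditions:

* bottom/top walls: electroosmotic slip u_t = slip_coeff * d(phi)/dx
  evaluated from the converged wall potential; zero penetration;
* membrane cells: solid, u = 0 on all their faces, no-slip on the
  fluid-facing interfaces (ghost at half cell);
* inlet/outlet: open reservoirs, P = 0 and zero normal-velocity
  gradient.

The operator matrix depends only on the mesh, so it is factorized once
(sparse LU) and reused; each call only rebuilds the right-hand side
from the current (c+, c-, phi) fields.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._discretize import Discretization, TransportParams


class StokesOperator:
    def __init__(self, disc: Discretization):
        self.disc = disc
        nx, ny = disc.nx, disc.ny
        self.n_u = ny * (nx + 1)
        self.n_v = (ny + 1) * nx
        self.n_p = ny * nx
        self.n = self.n_u + self.n_v + self.n_p
        mem2 = disc.mem.reshape(ny, nx)

        iu = lambda j, i: j * (nx + 1) + i  # noqa: E731
        iv = lambda j, i: self.n_u + j * nx + i  # noqa: E731
        ip = lambda j, i: self.n_u + self.n_v + j * nx + i  # noqa: E731
        self._iu, self._iv, self._ip = iu, iv, ip

        u_solid = np.zeros((ny, nx + 1), bool)
        u_solid[:, 1:nx] = mem2[:, :-1] | mem2[:, 1:]
        u_solid[:, 0] = mem2[:, 0]
        u_solid[:, nx] = mem2[:, -1]
        v_solid = np.zeros((ny + 1, nx), bool)
        v_solid[0, :] = True
        v_solid[ny, :] = True
        v_solid[1:ny, :] = mem2[:-1, :] | mem2[1:, :]
        self.u_solid, self.v_solid = u_solid, v_solid

        dx, dy, xc, yc = disc.dx, disc.dy, disc.xc, disc.yc
        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        # ---- x-momentum -------------------------------------------------
        # bookkeeping for RHS: (row, coefficient) pairs where a slip or
        # no-slip ghost constant multiplies into the right-hand side.
        self._slip_rows_bottom = []  # (row, i_face, coeff)
        self._slip_rows_top = []
        for j in range(ny):
            for i in range(nx + 1):
                r = iu(j, i)
                if u_solid[j, i]:
                    add(r, r, 1.0)
                    continue
                # x-direction viscous fluxes
                if i <= nx - 1:
                    cE = dy[j] / dx[i]
                    add(r, iu(j, i + 1), cE)
                    add(r, r, -cE)
                if i >= 1:
                    cW = dy[j] / dx[i - 1]
                    add(r, iu(j, i - 1), cW)
                    add(r, r, -cW)
                gx = (
                    xc[i] - xc[i - 1]
                    if 1 <= i <= nx - 1
                    else (xc[0] - disc.x_faces[0] if i == 0 else disc.x_faces[-1] - xc[-1])
                )
                # y-direction viscous fluxes
                if j == ny - 1:
                    coeff = 2.0 * gx / dy[j]
                    add(r, r, -coeff)
                    self._slip_rows_top.append((r, i, coeff))
                elif u_solid[j + 1, i]:
                    add(r, r, -2.0 * gx / dy[j])  # no-slip ghost at interface
                else:
                    cN = gx / (yc[j + 1] - yc[j])
                    add(r, iu(j + 1, i), cN)
                    add(r, r, -cN)
                if j == 0:
                    coeff = 2.0 * gx / dy[j]
                    add(r, r, -coeff)
                    self._slip_rows_bottom.append((r, i, coeff))
                elif u_solid[j - 1, i]:
                    add(r, r, -2.0 * gx / dy[j])
                else:
                    cS = gx / (yc[j] - yc[j - 1])
                    add(r, iu(j - 1, i), cS)
                    add(r, r, -cS)
                # pressure gradient (reservoir P = 0 outside inlet/outlet)
                if i >= 1:
                    add(r, ip(j, i - 1), dy[j])
                if i <= nx - 1:
                    add(r, ip(j, i), -dy[j])
        # ---- y-momentum -------------------------------------------------
        for j in range(ny + 1):
            for i in range(nx):
                r = iv(j, i)
                if v_solid[j, i]:
                    add(r, r, 1.0)
                    continue
                gy = yc[j] - yc[j - 1]
                cN = dx[i] / dy[j]
                add(r, iv(j + 1, i), cN)
                add(r, r, -cN)
                cS = dx[i] / dy[j - 1]
                add(r, iv(j - 1, i), cS)
                add(r, r, -cS)
                if i <= nx - 2:
                    if v_solid[j, i + 1]:
                        add(r, r, -2.0 * gy / dx[i])
                    else:
                        cE = gy / (xc[i + 1] - xc[i])
                        add(r, iv(j, i + 1), cE)
                        add(r, r, -cE)
                if i >= 1:
                    if v_solid[j, i - 1]:
                        add(r, r, -2.0 * gy / dx[i])
                    else:
                        cW = gy / (xc[i] - xc[i - 1])
                        add(r, iv(j, i - 1), cW)
                        add(r, r, -cW)
                add(r, ip(j - 1, i), dx[i])
                add(r, ip(j, i), -dx[i])
        # ---- continuity / solid pressure --------------------------------
        for j in range(ny):
            for i in range(nx):
                r = ip(j, i)
                if mem2[j, i]:
                    add(r, r, 1.0)
                    continue
                add(r, iu(j, i + 1), dy[j])
                add(r, iu(j, i), -dy[j])
                add(r, iv(j + 1, i), dx[i])
                add(r, iv(j, i), -dx[i])

        self.matrix = sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n)).tocsc()
        self.lu = spla.splu(self.matrix)
        # unit inlet-reservoir-pressure solution, used to impose zero net
        # through-flow (finite reservoirs build a counter-pressure head)
        b_p = np.zeros(self.n)
        for j in range(ny):
            if not u_solid[j, 0]:
                b_p[iu(j, 0)] = -dy[j]
        self._b_pressure = b_p
        self._u_pressure = self.lu.solve(b_p)

    def net_inflow(self, x: np.ndarray) -> float:
        """Volumetric flux per unit depth through the inlet section."""
        disc = self.disc
        ux0 = x[: self.n_u].reshape(disc.ny, disc.nx + 1)[:, 0]
        return float(np.sum(ux0 * disc.dy))

    # ------------------------------------------------------------------
    def _wall_phi_gradient(self, phi2: np.ndarray, j_row: int, delta_v: float) -> np.ndarray:
        """d(phi)/dx at every ux-face position along one wall-adjacent
        cell row (length nx+1), using reservoir ghosts at the ends."""
        disc = self.disc
        nx = disc.nx
        g = np.empty(nx + 1)
        g[1:nx] = (phi2[j_row, 1:] - phi2[j_row, :-1]) / (disc.xc[1:] - disc.xc[:-1])
        g[0] = (phi2[j_row, 0] - delta_v) / (0.5 * disc.dx[0])
        g[nx] = (0.0 - phi2[j_row, -1]) / (0.5 * disc.dx[-1])
        return g

    def rhs(self, par: TransportParams, cp: np.ndarray, cm: np.ndarray, phi: np.ndarray,
            kappa: float, slip_bottom: float, slip_top: float) -> np.ndarray:
        """Right-hand side from the current charge/potential fields."""
        disc = self.disc
        nx, ny = disc.nx, disc.ny
        b = np.zeros(self.n)
        rho = (par.z_plus * cp + par.z_minus * cm + np.where(disc.mem, par.n_fixed, 0.0)).reshape(ny, nx)
        phi2 = phi.reshape(ny, nx)
        dx, dy, xc, yc = disc.dx, disc.dy, disc.xc, disc.yc

        # body force on x-momentum rows: equation ... + f_x * V = 0 with
        # f_x = -kappa * rho * dphi/dx  ->  b -= f_x * V
        for j in range(ny):
            for i in range(nx + 1):
                if self.u_solid[j, i]:
                    continue
                if 1 <= i <= nx - 1:
                    gx = xc[i] - xc[i - 1]
                    dphidx = (phi2[j, i] - phi2[j, i - 1]) / gx
                    rho_f = 0.5 * (rho[j, i] + rho[j, i - 1])
                elif i == 0:
                    gx = xc[0] - disc.x_faces[0]
                    dphidx = (phi2[j, 0] - par.delta_v) / gx
                    rho_f = rho[j, 0]
                else:
                    gx = disc.x_faces[-1] - xc[-1]
                    dphidx = (0.0 - phi2[j, -1]) / gx
                    rho_f = rho[j, -1]
                b[self._iu(j, i)] += kappa * rho_f * dphidx * gx * dy[j]
        for j in range(1, ny):
            for i in range(nx):
                if self.v_solid[j, i]:
                    continue
                gy = yc[j] - yc[j - 1]
                dphidy = (phi2[j, i] - phi2[j - 1, i]) / gy
                rho_f = 0.5 * (rho[j, i] + rho[j - 1, i])
                b[self._iv(j, i)] += kappa * rho_f * dphidy * gy * dx[i]

        # slip ghosts
        g_bot = self._wall_phi_gradient(phi2, 0, par.delta_v)
        g_top = self._wall_phi_gradient(phi2, ny - 1, par.delta_v)
        for r, i, coeff in self._slip_rows_bottom:
            b[r] -= coeff * slip_bottom * g_bot[i]
        for r, i, coeff in self._slip_rows_top:
            b[r] -= coeff * slip_top * g_top[i]
        return b

    def solve(self, par: TransportParams, cp, cm, phi, kappa, slip_bottom, slip_top,
              flow_bc: str = "zero_net_flow"):
        """Solve for (ux, uy, P), returned as scaled MAC arrays.

        ``flow_bc="open"`` leaves both reservoirs at ambient pressure;
        ``"zero_net_flow"`` (the finite-reservoir steady state) adds the
        inlet pressure head that cancels the net electroosmotic
        through-flow, leaving the recirculating part of the flow.
        """
        b = self.rhs(par, cp, cm, phi, kappa, slip_bottom, slip_top)
        x = self.lu.solve(b)
        if flow_bc == "zero_net_flow":
            q0 = self.net_inflow(x)
            qp = self.net_inflow(self._u_pressure)
            if abs(qp) > 0.0:
                x = x - (q0 / qp) * self._u_pressure
        elif flow_bc != "open":
            raise ValueError("flow_bc must be 'open' or 'zero_net_flow'")
        nx, ny = self.disc.nx, self.disc.ny
        ux = x[: self.n_u].reshape(ny, nx + 1)
        uy = x[self.n_u: self.n_u + self.n_v].reshape(ny + 1, nx)
        P = x[self.n_u + self.n_v:].reshape(ny, nx)
        return ux, uy, P

    def residual(self, par, ux, uy, P, cp, cm, phi, kappa, slip_bottom, slip_top,
                 flow_bc: str = "zero_net_flow") -> np.ndarray:
        """Momentum + continuity residual of a given state (scaled).

        Under ``zero_net_flow`` the (unknown) reservoir pressure head is
        an auxiliary variable fixed by the zero-net-flux constraint, so
        its component is projected out of the raw residual and the
        constraint violation (net inflow) is reported in its place.
        """
        x = np.concatenate([ux.ravel(), uy.ravel(), P.ravel()])
        b = self.rhs(par, cp, cm, phi, kappa, slip_bottom, slip_top)
        r = self.matrix @ x - b
        if flow_bc == "zero_net_flow":
            bp = self._b_pressure
            r = r - (bp @ r) / (bp @ bp) * bp
            r = np.append(r, self.net_inflow(x))
        return r

    def divergence(self, ux: np.ndarray, uy: np.ndarray) -> np.ndarray:
        """Cell-wise scaled velocity divergence (per unit cell area)."""
        disc = self.disc
        div = (
            (ux[:, 1:] - ux[:, :-1]) * disc.dy[:, None]
            + (uy[1:, :] - uy[:-1, :]) * disc.dx[None, :]
        )
        return div / np.outer(disc.dy, disc.dx)
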