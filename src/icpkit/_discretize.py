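"""Finite-volume discretization kernels for the ion-transport equations.

Everything here works in the nondimensional variables of
:class:`~icpkit.system.ScaledSystem`: concentrations in units of c0,
potential in thermal voltages, lengths in channel heights, velocities in
the electroosmotic reference.  The combined diffusion/electromigration
face flux uses Scharfetter-Gummel exponential fitting (exact for the 1D
constant-coefficient drift-diffusion problem, oscillation-free at steep
depletion fronts); the advective ion flux is first-order upwind.

Flux convention: for a face between cells L and R the flux J is
positive from L to R; a cell's residual is the sum of its *outward*
area-weighted fluxes divided by the cell area, minus any volumetric
source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import Mesh
from .system import ScaledSystem


def bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), computed stably for all x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1.0e-8
    big_pos = x > 500.0
    big_neg = x < -500.0
    mid = ~(small | big_pos | big_neg)
    xs = x[small]
    out[small] = 1.0 - 0.5 * xs + xs * xs / 12.0
    out[big_pos] = x[big_pos] * np.exp(-x[big_pos])
    out[big_neg] = -x[big_neg]
    xm = x[mid]
    out[mid] = xm / np.expm1(xm)
    return out


def dbernoulli(x: np.ndarray) -> np.ndarray:
    """Derivative B'(x), stable companion to :func:`bernoulli`."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1.0e-6
    big_pos = x > 300.0
    big_neg = x < -300.0
    mid = ~(small | big_pos | big_neg)
    xs = x[small]
    out[small] = -0.5 + xs / 6.0 - xs**3 / 180.0
    out[big_pos] = (1.0 - x[big_pos]) * np.exp(-x[big_pos])
    out[big_neg] = -1.0
    xm = x[mid]
    em = np.expm1(xm)
    out[mid] = (em - xm * (em + 1.0)) / (em * em)
    return out


@dataclass(frozen=True)
class TransportParams:
    """Scaled coefficients consumed by the residual kernels."""

    z_plus: float
    z_minus: float
    d_plus: float
    d_minus: float
    peclet: float
    lam2: float        # 2 * lambda_tilde^2 (Poisson coefficient)
    n_fixed: float     # membrane fixed charge / c0 (negative)
    c_donnan: float    # pinned membrane anion concentration / c0
    delta_v: float     # inlet potential in thermal voltages (outlet = 0)

    @classmethod
    def from_scaled(cls, scaled: ScaledSystem, z_plus: int, z_minus: int,
                    c_donnan: float, delta_v: float | None = None) -> "TransportParams":
        return cls(
            z_plus=float(z_plus),
            z_minus=float(z_minus),
            d_plus=scaled.d_plus,
            d_minus=scaled.d_minus,
            peclet=scaled.peclet,
            lam2=2.0 * scaled.lambda_tilde**2,
            n_fixed=scaled.n_fixed,
            c_donnan=c_donnan,
            delta_v=scaled.delta_v if delta_v is None else delta_v,
        )


class Discretization:
    """Face connectivity and geometric factors of a scaled mesh.

    Face groups:

    * interior x-faces (between horizontally adjacent cells),
    * interior y-faces,
    * west boundary faces (inlet, Dirichlet ghost at phi = delta_v, c = 1),
    * east boundary faces (outlet, ghost at phi = 0, c = 1).

    Top/bottom walls are zero-flux for ions and potential and need no
    face entries.  ``*_anion`` masks implement the cation-only membrane:
    anion flux is blocked through every face touching a membrane cell.
    """

    def __init__(self, mesh: Mesh, scaled: ScaledSystem, cation_only: bool = True,
                 membrane_d_factor: float = 1.0):
        L = scaled.length
        self.mesh = mesh
        self.scaled = scaled
        self.nx, self.ny = mesh.nx, mesh.ny
        self.N = mesh.n_cells
        self.dx = mesh.dx / L
        self.dy = mesh.dy / L
        self.xc = mesh.xc / L
        self.yc = mesh.yc / L
        self.x_faces = mesh.x_faces / L
        self.y_faces = mesh.y_faces / L
        self.length_x = self.x_faces[-1] - self.x_faces[0]
        self.mem = mesh.membrane_mask.ravel()
        self.A = np.outer(self.dy, self.dx).ravel()
        nx, ny = self.nx, self.ny

        jj, ii = [a.ravel() for a in np.meshgrid(np.arange(ny), np.arange(nx - 1), indexing="ij")]
        self.fx_kL = jj * nx + ii
        self.fx_kR = self.fx_kL + 1
        self.fx_h = self.xc[ii + 1] - self.xc[ii]
        self.fx_area = self.dy[jj]
        self.fx_uj = jj
        self.fx_ui = ii + 1
        self.fx_i = ii  # cell index left of the face
        memL, memR = self.mem[self.fx_kL], self.mem[self.fx_kR]
        self.fx_anion = ~(memL | memR) if cation_only else np.ones(len(jj), bool)
        cell_fac = np.where(self.mem, membrane_d_factor, 1.0)
        self.fx_dfac = _harmonic(cell_fac[self.fx_kL], cell_fac[self.fx_kR])

        jj, ii = [a.ravel() for a in np.meshgrid(np.arange(ny - 1), np.arange(nx), indexing="ij")]
        self.fy_kL = jj * nx + ii
        self.fy_kR = self.fy_kL + nx
        self.fy_h = self.yc[jj + 1] - self.yc[jj]
        self.fy_area = self.dx[ii]
        self.fy_uj = jj + 1
        self.fy_ui = ii
        memL, memR = self.mem[self.fy_kL], self.mem[self.fy_kR]
        self.fy_anion = ~(memL | memR) if cation_only else np.ones(len(jj), bool)
        self.fy_dfac = _harmonic(cell_fac[self.fy_kL], cell_fac[self.fy_kR])

        jb = np.arange(ny)
        self.bw_k = jb * nx
        self.bw_h = np.full(ny, 0.5 * self.dx[0])
        self.bw_area = self.dy.copy()
        self.bw_uj = jb
        self.be_k = jb * nx + nx - 1
        self.be_h = np.full(ny, 0.5 * self.dx[-1])
        self.be_area = self.dy.copy()
        self.be_uj = jb
        self.bw_anion = ~self.mem[self.bw_k] if cation_only else np.ones(ny, bool)
        self.be_anion = ~self.mem[self.be_k] if cation_only else np.ones(ny, bool)
        self.bw_dfac = cell_fac[self.bw_k]
        self.be_dfac = cell_fac[self.be_k]
        self.cation_only = cation_only
        self.membrane_d_factor = membrane_d_factor


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


class _COO:
    """Tiny accumulator for vectorized sparse-matrix assembly."""

    def __init__(self) -> None:
        self.rows: list[np.ndarray] = []
        self.cols: list[np.ndarray] = []
        self.vals: list[np.ndarray] = []

    def add(self, rows, cols, vals) -> None:
        self.rows.append(np.asarray(rows))
        self.cols.append(np.asarray(cols))
        self.vals.append(np.asarray(vals, float))

    def matrix(self, shape) -> sp.csr_matrix:
        return sp.coo_matrix(
            (np.concatenate(self.vals), (np.concatenate(self.rows), np.concatenate(self.cols))),
            shape=shape,
        ).tocsr()


def species_face_fluxes(
    disc: Discretization,
    par: TransportParams,
    z: float,
    d: float,
    c: np.ndarray,
    phi: np.ndarray,
    ux: np.ndarray,
    uy: np.ndarray,
    group: str,
) -> np.ndarray:
    """Scaled molar flux (per face, L->R positive) of one species through
    one face group ("x", "y", "west", "east")."""
    if group == "x":
        kL, kR, h, dfac = disc.fx_kL, disc.fx_kR, disc.fx_h, disc.fx_dfac
        uf = ux[disc.fx_uj, disc.fx_ui]
        cL, cR = c[kL], c[kR]
        psi = z * (phi[kR] - phi[kL])
    elif group == "y":
        kL, kR, h, dfac = disc.fy_kL, disc.fy_kR, disc.fy_h, disc.fy_dfac
        uf = uy[disc.fy_uj, disc.fy_ui]
        cL, cR = c[kL], c[kR]
        psi = z * (phi[kR] - phi[kL])
    elif group == "west":
        k, h, dfac = disc.bw_k, disc.bw_h, disc.bw_dfac
        uf = ux[disc.bw_uj, 0]
        cL, cR = np.ones(len(k)), c[k]
        psi = z * (phi[k] - par.delta_v)
    elif group == "east":
        k, h, dfac = disc.be_k, disc.be_h, disc.be_dfac
        uf = ux[disc.be_uj, disc.nx]
        cL, cR = c[k], np.ones(len(k))
        psi = z * (0.0 - phi[k])
    else:  # pragma: no cover
        raise ValueError(group)
    j_dd = d * dfac / h * (bernoulli(psi) * cL - bernoulli(-psi) * cR)
    j_adv = par.peclet * uf * np.where(uf > 0.0, cL, cR)
    return j_dd + j_adv


def pnp_residual(
    disc: Discretization,
    par: TransportParams,
    cp: np.ndarray,
    cm: np.ndarray,
    phi: np.ndarray,
    ux: np.ndarray,
    uy: np.ndarray,
    want_jacobian: bool = False,
):
    """Residual (and optionally the analytic Jacobian) of the steady
    coupled Nernst-Planck/Poisson block at frozen velocity.

    Unknown layout: [c+ (N), c- (N), phi (N)].  Anion rows of membrane
    cells are replaced by the Donnan pinning c- = c_donnan when the
    membrane is cation-only.
    """
    N = disc.N
    R = np.zeros(3 * N)
    coo = _COO() if want_jacobian else None
    invA = 1.0 / disc.A

    def do_species(off: int, z: float, d: float, c: np.ndarray, active_masks) -> None:
        # interior faces
        for (kL, kR, h, area, uj, ui, dfac, act, uarr) in (
            (disc.fx_kL, disc.fx_kR, disc.fx_h, disc.fx_area, disc.fx_uj, disc.fx_ui,
             disc.fx_dfac, active_masks[0], ux),
            (disc.fy_kL, disc.fy_kR, disc.fy_h, disc.fy_area, disc.fy_uj, disc.fy_ui,
             disc.fy_dfac, active_masks[1], uy),
        ):
            if act is not None:
                kL, kR, h, area = kL[act], kR[act], h[act], area[act]
                uj, ui, dfac = uj[act], ui[act], dfac[act]
            uf = uarr[uj, ui]
            de = d * dfac
            psi = z * (phi[kR] - phi[kL])
            Bp, Bm = bernoulli(psi), bernoulli(-psi)
            up = uf > 0.0
            J = de / h * (Bp * c[kL] - Bm * c[kR]) + par.peclet * uf * np.where(up, c[kL], c[kR])
            contrib = area * J
            np.add.at(R, off + kL, contrib)
            np.add.at(R, off + kR, -contrib)
            if coo is not None:
                dBp, dBm = dbernoulli(psi), dbernoulli(-psi)
                dJdcL = de / h * Bp + par.peclet * uf * up
                dJdcR = -de / h * Bm + par.peclet * uf * (~up)
                dJdpsi = de / h * (dBp * c[kL] + dBm * c[kR])
                dJdphiL = -z * dJdpsi
                dJdphiR = z * dJdpsi
                aL = area * invA[kL]
                aR = area * invA[kR]
                coff = off  # concentration column block matches row block
                for col, dv in ((coff + kL, dJdcL), (coff + kR, dJdcR),
                                (2 * N + kL, dJdphiL), (2 * N + kR, dJdphiR)):
                    coo.add(off + kL, col, aL * dv)
                    coo.add(off + kR, col, -aR * dv)
        # west boundary (ghost on the left)
        act = active_masks[2]
        k, h, area, uj, dfac = disc.bw_k, disc.bw_h, disc.bw_area, disc.bw_uj, disc.bw_dfac
        if act is not None:
            k, h, area, uj, dfac = k[act], h[act], area[act], uj[act], dfac[act]
        uf = ux[uj, 0]
        de = d * dfac
        psi = z * (phi[k] - par.delta_v)
        Bp, Bm = bernoulli(psi), bernoulli(-psi)
        up = uf > 0.0
        J = de / h * (Bp * 1.0 - Bm * c[k]) + par.peclet * uf * np.where(up, 1.0, c[k])
        np.add.at(R, off + k, -area * J)
        if coo is not None:
            dJdcR = -de / h * Bm + par.peclet * uf * (~up)
            dJdpsi = de / h * (dbernoulli(psi) * 1.0 + dbernoulli(-psi) * c[k])
            ak = area * invA[k]
            coo.add(off + k, off + k, -ak * dJdcR)
            coo.add(off + k, 2 * N + k, -ak * (z * dJdpsi))
        # east boundary (ghost on the right)
        act = active_masks[3]
        k, h, area, uj, dfac = disc.be_k, disc.be_h, disc.be_area, disc.be_uj, disc.be_dfac
        if act is not None:
            k, h, area, uj, dfac = k[act], h[act], area[act], uj[act], dfac[act]
        uf = ux[uj, disc.nx]
        de = d * dfac
        psi = z * (0.0 - phi[k])
        Bp, Bm = bernoulli(psi), bernoulli(-psi)
        up = uf > 0.0
        J = de / h * (Bp * c[k] - Bm * 1.0) + par.peclet * uf * np.where(up, c[k], 1.0)
        np.add.at(R, off + k, area * J)
        if coo is not None:
            dJdcL = de / h * Bp + par.peclet * uf * up
            dJdpsi = de / h * (dbernoulli(psi) * c[k] + dbernoulli(-psi) * 1.0)
            ak = area * invA[k]
            coo.add(off + k, off + k, ak * dJdcL)
            coo.add(off + k, 2 * N + k, ak * (-z * dJdpsi))

    do_species(0, par.z_plus, par.d_plus, cp, (None, None, None, None))
    anion_masks = (disc.fx_anion, disc.fy_anion, disc.bw_anion, disc.be_anion)
    do_species(N, par.z_minus, par.d_minus, cm, anion_masks)

    # Poisson flux part
    for (kL, kR, h, area) in (
        (disc.fx_kL, disc.fx_kR, disc.fx_h, disc.fx_area),
        (disc.fy_kL, disc.fy_kR, disc.fy_h, disc.fy_area),
    ):
        F = -par.lam2 * (phi[kR] - phi[kL]) / h
        contrib = area * F
        np.add.at(R, 2 * N + kL, contrib)
        np.add.at(R, 2 * N + kR, -contrib)
        if coo is not None:
            g = par.lam2 / h * area
            coo.add(2 * N + kL, 2 * N + kL, g * invA[kL])
            coo.add(2 * N + kL, 2 * N + kR, -g * invA[kL])
            coo.add(2 * N + kR, 2 * N + kR, g * invA[kR])
            coo.add(2 * N + kR, 2 * N + kL, -g * invA[kR])
    for (k, h, area, phi_g) in (
        (disc.bw_k, disc.bw_h, disc.bw_area, par.delta_v),
        (disc.be_k, disc.be_h, disc.be_area, 0.0),
    ):
        F = par.lam2 * (phi[k] - phi_g) / h
        np.add.at(R, 2 * N + k, area * F)
        if coo is not None:
            coo.add(2 * N + k, 2 * N + k, par.lam2 / h * area * invA[k])

    # intensive form + sources
    R[:N] *= invA
    R[N:2 * N] *= invA
    R[2 * N:] *= invA
    n_cell = np.where(disc.mem, par.n_fixed, 0.0)
    R[2 * N:] -= par.z_plus * cp + par.z_minus * cm + n_cell
    if coo is not None:
        k_all = np.arange(N)
        coo.add(2 * N + k_all, k_all, np.full(N, -par.z_plus))
        coo.add(2 * N + k_all, N + k_all, np.full(N, -par.z_minus))

    # Donnan pinning of the membrane anion concentration
    if disc.cation_only:
        k_mem = np.flatnonzero(disc.mem)
        R[N + k_mem] = cm[k_mem] - par.c_donnan
        if coo is not None:
            coo.add(N + k_mem, N + k_mem, np.ones(len(k_mem)))

    if coo is None:
        return R, None
    return R, coo.matrix((3 * N, 3 * N))
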