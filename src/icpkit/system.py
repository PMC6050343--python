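"""Electrokinetic case definition and nondimensionalization.

An :class:`ElectrokineticSystem` bundles everything that defines one
simulation case: physical constants, the binary electrolyte, the device
geometry, the fixed-charge membrane, the wall zeta potentials and the
applied axial field.  :func:`nondimensionalize` derives the reference
scales and dimensionless groups the solver works in.

Reference scales
----------------
length      channel height H
concentration  reservoir concentration c0
potential   thermal voltage R*T/F
velocity    electroosmotic scale eps*(R*T/F)*E/mu (diffusive D/H at E=0)
pressure    mu*u_ref/H
time        H/u_ref
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import PhysicalConstants
from .geometry import DeviceGeometry


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Binary electrolyte (defaults: 10 mM NaCl, literature diffusivities)."""

    z_plus: int = 1
    z_minus: int = -1
    D_plus: float = 1.33e-9
    D_minus: float = 2.03e-9
    c0: float = 10.0  # mol/m^3 == 10 mM

    def __post_init__(self) -> None:
        if not (self.z_plus > 0 > self.z_minus):
            raise ValueError("need z_plus > 0 > z_minus")
        if self.D_plus <= 0 or self.D_minus <= 0:
            raise ValueError("ion diffusivities must be positive")
        if self.c0 <= 0:
            raise ValueError("reservoir concentration c0 must be positive")


@dataclass(frozen=True)
class MembraneSpec:
    """Ion-permselective membrane carrying uniform immobile negative charge.

    ``fixed_charge_concentration`` is the signed equivalent concentration
    of the immobile charge in mol/m^3 (negative for a cation-selective
    membrane); ``cation_only`` additionally zeroes the anion flux through
    every membrane face.  ``diffusivity_factor`` is the porosity/
    tortuosity reduction of ion diffusivities inside the printed polymer
    relative to free solution; it sets the membrane branch conductance
    and thereby how strongly the channel polarizes.
    """

    fixed_charge_concentration: float = -100.0
    cation_only: bool = True
    diffusivity_factor: float = 0.01

    def __post_init__(self) -> None:
        if self.fixed_charge_concentration >= 0.0:
            raise ValueError("fixed_charge_concentration must be negative")
        if not (0.0 < self.diffusivity_factor <= 1.0):
            raise ValueError("diffusivity_factor must be in (0, 1]")

    def donnan_anion_concentration(self, c0: float) -> float:
        """Equilibrium co-ion (anion) concentration inside the membrane.

        Ideal Donnan equilibrium for a symmetric binary electrolyte:
        C+ * C- = c0^2 with C+ - C- = |N|.
        """
        n = abs(self.fixed_charge_concentration)
        return 0.5 * (-n + np.sqrt(n * n + 4.0 * c0 * c0))


@dataclass(frozen=True)
class WallSpec:
    """Wall zeta potentials for the electroosmotic slip condition.

    Defaults: polystyrene bottom -60 mV, PDMS top -40 mV. The slip
    velocity is u_s = -eps*zeta*E_t/mu with E_t the tangential field
    evaluated from the converged potential at the wall.
    """

    zeta_bottom: float = -60.0e-3
    zeta_top: float = -40.0e-3

    def __post_init__(self) -> None:
        if self.zeta_bottom >= 0.0 or self.zeta_top >= 0.0:
            raise ValueError("wall zeta potentials must be negative")


@dataclass(frozen=True)
class DriveSpec:
    """Applied axial electric field (V/m). Default 3.6 V/mm."""

    axial_field: float = 3.6e3

    def __post_init__(self) -> None:
        if self.axial_field < 0.0:
            raise ValueError("axial_field must be >= 0")

    def total_voltage(self, channel_length: float) -> float:
        return self.axial_field * channel_length


@dataclass(frozen=True)
class ElectrokineticSystem:
    """One complete simulation case."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    electrolyte: ElectrolyteSpec = field(default_factory=ElectrolyteSpec)
    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    walls: WallSpec = field(default_factory=WallSpec)
    drive: DriveSpec = field(default_factory=DriveSpec)

    def with_drive(self, axial_field: float) -> "ElectrokineticSystem":
        return ElectrokineticSystem(
            constants=self.constants,
            electrolyte=self.electrolyte,
            geometry=self.geometry,
            membrane=self.membrane,
            walls=self.walls,
            drive=DriveSpec(axial_field=axial_field),
        )

    @property
    def debye_length(self) -> float:
        """Physical Debye length of the bulk electrolyte, m."""
        k = self.constants
        e = self.electrolyte
        ionic = e.c0 * (e.z_plus**2 - e.z_plus * e.z_minus)  # z+^2 c+ + z-^2 c-
        # for a z+:z- electrolyte electroneutral bulk: c+ = c0, c- = c0*z+/|z-|
        return float(np.sqrt(k.eps * k.R * k.T / (k.F**2 * ionic)))


@dataclass(frozen=True)
class ScaledSystem:
    """Reference scales and dimensionless groups for one case.

    ``lambda_tilde`` is the *numerical* dimensionless Debye length
    actually used by the Poisson operator (possibly inflated, see
    ``debye_scale``); ``lambda_tilde_physical`` is the unscaled one.
    """

    # reference scales (SI)
    length: float
    concentration: float
    potential: float
    velocity: float
    pressure: float
    time: float
    diffusivity: float
    # dimensionless groups
    lambda_tilde: float
    lambda_tilde_physical: float
    peclet: float
    kappa: float          # electric body-force coupling F*c0*V_T*L/(mu*u_ref)
    delta_v: float        # applied voltage drop over the domain, in V_T
    d_plus: float
    d_minus: float
    n_fixed: float        # membrane fixed charge / c0
    slip_coeff_bottom: float  # u_slip~ = slip_coeff * d(phi~)/d(x~) at wall
    slip_coeff_top: float
    debye_scale: float    # inflation factor applied to the Debye length

    def scale_concentration(self, c: np.ndarray | float) -> np.ndarray | float:
        return c / self.concentration

    def unscale_concentration(self, c: np.ndarray | float) -> np.ndarray | float:
        return c * self.concentration

    def scale_potential(self, v):
        return v / self.potential

    def unscale_potential(self, v):
        return v * self.potential

    def scale_velocity(self, u):
        return u / self.velocity

    def unscale_velocity(self, u):
        return u * self.velocity

    def scale_pressure(self, p):
        return p / self.pressure

    def unscale_pressure(self, p):
        return p * self.pressure

    def scale_length(self, x):
        return x / self.length

    def unscale_length(self, x):
        return x * self.length

    def scale_time(self, t):
        return t / self.time

    def unscale_time(self, t):
        return t * self.time


def nondimensionalize(
    constants: PhysicalConstants,
    electrolyte: ElectrolyteSpec,
    geometry: DeviceGeometry,
    drive: DriveSpec,
    membrane: MembraneSpec | None = None,
    walls: WallSpec | None = None,
    debye_scale: float = 1.0,
) -> ScaledSystem:
    """Derive reference scales and dimensionless groups.

    ``debye_scale`` multiplies the Debye length entering the scaled
    Poisson equation (the standard device-scale rescaling; the physical
    double layer at 10 mM is ~3 nm and unresolvable on a 17 um channel).
    All scale/unscale round trips are exact to floating point.
    """
    k = constants
    H = geometry.channel_height
    vt = k.thermal_voltage
    E = drive.axial_field
    u_ref = k.eps * vt * E / k.mu if E > 0 else electrolyte.D_plus / H
    d_ref = electrolyte.D_plus
    lam = np.sqrt(
        k.eps * k.R * k.T
        / (k.F**2 * electrolyte.c0 * (electrolyte.z_plus**2 - electrolyte.z_plus * electrolyte.z_minus))
    )
    walls = walls or WallSpec()
    slip = lambda zeta: k.eps * zeta * vt / (k.mu * H * u_ref)  # noqa: E731
    return ScaledSystem(
        length=H,
        concentration=electrolyte.c0,
        potential=vt,
        velocity=u_ref,
        pressure=k.mu * u_ref / H,
        time=H / u_ref,
        diffusivity=d_ref,
        lambda_tilde=float(lam) * debye_scale / H,
        lambda_tilde_physical=float(lam) / H,
        peclet=u_ref * H / d_ref,
        # The electric body force is -kappa * rho~ * grad(phi~) with rho~
        # from the *inflated* Poisson operator; dividing by debye_scale^2
        # keeps the physical electrohydrodynamic coupling kappa*lambda~^2
        # invariant, so electroosmotic magnitudes stay physical.
        kappa=k.F * electrolyte.c0 * vt * H / (k.mu * u_ref) / debye_scale**2,
        delta_v=E * geometry.channel_length / vt,
        d_plus=electrolyte.D_plus / d_ref,
        d_minus=electrolyte.D_minus / d_ref,
        n_fixed=(membrane.fixed_charge_concentration / electrolyte.c0) if membrane else 0.0,
        slip_coeff_bottom=slip(walls.zeta_bottom),
        slip_coeff_top=slip(walls.zeta_top),
        debye_scale=debye_scale,
    )
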