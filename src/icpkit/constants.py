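"""Physical constants and fluid properties.

All quantities are SI. The defaults describe a dilute aqueous NaCl
electrolyte at room temperature, the carrier used throughout the
microchannel preconcentrator model.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants and fluid properties of the electrolyte.

    Attributes
    ----------
    F : float
        Faraday constant, C/mol.
    R : float
        Molar gas constant, J/(mol K).
    T : float
        Absolute temperature, K.
    eps : float
        Electric permittivity of water (eps_0 * eps_r), F/m.
    mu : float
        Dynamic viscosity of water, Pa s.
    rho : float
        Mass density of water, kg/m^3.
    """

    F: float = 96485.332
    R: float = 8.314462
    T: float = 298.15
    eps: float = 6.95e-10
    mu: float = 1.0e-3
    rho: float = 1.0e3

    def __post_init__(self) -> None:
        for name in ("F", "R", "T", "eps", "mu", "rho"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"PhysicalConstants.{name} must be strictly positive")
        vt = self.thermal_voltage
        if 273.0 < self.T < 333.0 and not (0.020 < vt < 0.030):
            raise ValueError(
                f"thermal voltage R*T/F = {vt:.4g} V outside the (20, 30) mV "
                "range expected for liquid water temperatures"
            )

    @property
    def thermal_voltage(self) -> float:
        """Thermal voltage R*T/F in volts (~25.7 mV at 298 K)."""
        return self.R * self.T / self.F
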