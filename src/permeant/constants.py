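"""Physical constants and the internal unit system.

Internal units are fixed package-wide: length in Å, time in ps, energy in
kJ/mol, temperature in K.  Conversions to reporting units (cm/s for
permeability, kg/m³ for densities) happen only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kJ/mol/K (equals the molar gas constant R in kJ/mol/K).
KB = 0.008314462618

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Boltzmann constant in J/K (for per-molecule hydrodynamic formulas).
KB_J = 1.380649e-23

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 310.0

#: Molar mass of molecular oxygen, g/mol.  The coarse-grained bead that
#: represents O2 carries a standard assigned mass of 36 g/mol, but density
#: bookkeeping uses the molecular value.
O2_MOLAR_MASS = 32.0

#: Conversion factor: 1 Å/ps expressed in cm/s.
ANGSTROM_PER_PS_TO_CM_PER_S = 1.0e4

#: Conversion factor: 1 m²/s expressed in Å²/ps.
M2_PER_S_TO_A2_PER_PS = 1.0e8


def kBT(T: float) -> float:
    """Thermal energy kB·T in kJ/mol at temperature ``T`` (K)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return KB * T


@dataclass(frozen=True)
class Constants:
    """Bundle of the physical constants an analysis run depends on."""

    kB: float = KB
    N_A: float = N_AVOGADRO
    temperature: float = DEFAULT_TEMPERATURE
    molar_mass: float = O2_MOLAR_MASS

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")

    @property
    def kBT(self) -> float:
        return self.kB * self.temperature
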