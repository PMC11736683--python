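"""Transfer free energies from mole-fraction solubilities.

In the Henry (ideal-dilute) regime the free energy of moving a gas from the
gas phase into a solvent follows from its mole-fraction solubility x:

    ΔG_solvation = −R·T·ln(x)

and the solvent→water transfer free energy decomposes as

    ΔG_transfer = ΔG_hydration(G→W) − ΔG_solvation(G→S)
                = R·T·ln(x_S / x_W).

The sign convention is transfer FROM the solvent TO water: positive for a
hydrophobic permeant that prefers the organic phase (e.g. O2 in
hexadecane).  R is kB expressed in kJ/mol/K, so all energies are kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .constants import KB
from .errors import ValidationError


@dataclass(frozen=True)
class SolubilityRecord:
    """Mole-fraction solubility of the permeant in one solvent.

    Parameters
    ----------
    solvent : str
        Solvent name (``"water"``, ``"hexadecane"``, ...).
    x : float
        Mole-fraction solubility, 0 < x < 1 (Henry regime).
    T : float
        Temperature in K.
    pressure : float
        Gas partial pressure in kPa (bookkeeping only; the ideal-dilute
        formula does not use it).
    """

    solvent: str
    x: float
    T: float = 300.0
    pressure: float = 101.325

    def __post_init__(self):
        if not (0.0 < self.x < 1.0):
            raise ValidationError(
                f"mole fraction must satisfy 0 < x < 1, got {self.x}"
            )
        if self.T <= 0:
            raise ValidationError(f"temperature must be positive, got {self.T}")


@dataclass(frozen=True)
class TransferResult:
    """Decomposed transfer free energy between a solvent and water (kJ/mol)."""

    dG_hydration: float
    dG_solvation: float
    solvent: str
    water: str
    T: float

    @property
    def dG_transfer(self) -> float:
        """ΔG_transfer = ΔG_hydration − ΔG_solvation, exactly by construction."""
        return self.dG_hydration - self.dG_solvation


def solvation_free_energy(rec: SolubilityRecord) -> float:
    """Gas→solvent solvation free energy −R·T·ln(x) in kJ/mol.

    Strictly positive for x < 1 (dissolving a dilute gas always costs free
    energy on the mole-fraction scale).
    """
    return -KB * rec.T * math.log(rec.x)


def transfer_free_energy(
    solvent: SolubilityRecord, water: SolubilityRecord
) -> TransferResult:
    """Solvent→water transfer free energy from two solubility records.

    Both records must be at the same temperature (within 0.01 K).  The
    result is positive when the permeant is more soluble in the solvent
    than in water.
    """
    if abs(solvent.T - water.T) > 0.01:
        raise ValidationError(
            f"temperature mismatch: {solvent.solvent} at {solvent.T} K vs "
            f"{water.solvent} at {water.T} K"
        )
    return TransferResult(
        dG_hydration=solvation_free_energy(water),
        dG_solvation=solvation_free_energy(solvent),
        solvent=solvent.solvent,
        water=water.solvent,
        T=solvent.T,
    )
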