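"""Glycerol mass-balance arithmetic and culture unit conversions.

Links the intracellular glycerol pool of *D. salina* to the extracellular
concentration produced when cells die and release their contents:

    C_ext [mol/L] = c_int [mol/L] * (v_eff * 1e-15 L/cell) * (n_dead * 1e3 cells/L)

with ``v_eff`` the effective released volume per dying cell in µm^3
(1 µm^3 = 1e-15 L) and ``n_dead`` the density of dying cells per mL of
medium. With ~4 M intracellular glycerol and ~3e5 dying cells/mL, an
effective volume of 58 µm^3 per cell yields ~70 µM extracellular glycerol.
The per-cell volume is kept as an explicit free input because a single
1-µm granule is numerically far too small to close this budget.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BudgetInputs",
    "released_concentration",
    "implied_volume",
    "od_to_cells",
    "OD600_CELLS_PER_ML",
]

#: Cells per mL per unit OD600 for H. salinarum cultures.
OD600_CELLS_PER_ML = 8e8

_UM3_TO_L = 1e-15  # 1 µm^3 in litres
_PER_ML_TO_PER_L = 1e3
_MOLAR_TO_MICROMOLAR = 1e6


def released_concentration(c_int: float, v_eff: float, n_dead: float) -> float:
    """Extracellular glycerol (µM) released by dying cells.

    Parameters
    ----------
    c_int : float
        Intracellular glycerol concentration, mol/L.
    v_eff : float
        Effective released volume per dying cell, µm^3.
    n_dead : float
        Dying cells per mL of medium.
    """
    if c_int < 0 or v_eff < 0 or n_dead < 0:
        raise ValueError("budget inputs must be non-negative")
    molar = c_int * (v_eff * _UM3_TO_L) * (n_dead * _PER_ML_TO_PER_L)
    return molar * _MOLAR_TO_MICROMOLAR


def implied_volume(c_ext: float, c_int: float, n_dead: float) -> float:
    """Per-cell released volume (µm^3) implied by an extracellular concentration.

    Exact algebraic inverse of :func:`released_concentration` in its
    ``v_eff`` argument.
    """
    if c_ext < 0:
        raise ValueError("c_ext must be non-negative")
    if c_int <= 0 or n_dead <= 0:
        raise ValueError("c_int and n_dead must be positive to invert the budget")
    molar = c_ext / _MOLAR_TO_MICROMOLAR
    return molar / (c_int * _UM3_TO_L * n_dead * _PER_ML_TO_PER_L)


def od_to_cells(od600: float) -> float:
    """Convert OD600 to cells/mL (8e8 cells/mL per OD unit)."""
    if od600 < 0:
        raise ValueError("od600 must be non-negative")
    return OD600_CELLS_PER_ML * od600


@dataclass(frozen=True)
class BudgetInputs:
    """Inputs of the glycerol release budget.

    c_int: intracellular glycerol, mol/L; v_eff: effective released volume
    per dying cell, µm^3; n_dead: dying cells per mL.
    """

    c_int: float
    v_eff: float
    n_dead: float

    def __post_init__(self) -> None:
        if self.c_int <= 0 or self.v_eff <= 0 or self.n_dead < 0:
            raise ValueError("c_int and v_eff must be > 0 and n_dead >= 0")

    def released_concentration(self) -> float:
        """Extracellular glycerol in µM for these inputs."""
        return released_concentration(self.c_int, self.v_eff, self.n_dead)
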