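"""Extracellular mass balances coupled to the population model.

Batch operation with constant working volume: substrate/metabolite balances
are written per litre of culture.  Viable cell density ``X_V`` is carried in
cells/mL throughout the package (matching how such densities are reported),
so a factor of 1000 converts it to cells/L inside the per-litre balances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from cyclepbm.kinetics import SubstrateState, limiting_factors
from cyclepbm.params import ModelParameters

__all__ = [
    "CultureState",
    "CELLS_PER_ML_TO_PER_L",
    "substrate_rates",
    "lactate_rate",
    "mab_rate",
    "dead_cell_rate",
    "viability",
]

#: X_V (cells/mL) -> cells/L conversion used by the per-litre balances.
CELLS_PER_ML_TO_PER_L = 1.0e3


@dataclass
class CultureState:
    """Extracellular culture state for a batch run (constant volume V, mL)."""

    Glu: float = 4.0     # mM
    Glc: float = 25.0    # mM
    Lac: float = 0.0     # mM
    mAb: float = 0.0     # mg/L
    X_D: float = 0.0     # cells/mL
    V: float = 100.0     # mL

    def __post_init__(self) -> None:
        for name in ("Glu", "Glc", "Lac", "mAb", "X_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.V <= 0:
            raise ValueError("V must be positive")

    @property
    def substrates(self) -> SubstrateState:
        return SubstrateState(Glu=self.Glu, Glc=self.Glc, Lac=self.Lac)


def substrate_rates(
    mu: float, X_V: float, params: ModelParameters
) -> tuple[float, float]:
    """(dGlu/dt, dGlc/dt) in mM/h for growth rate mu (1/h) and X_V (cells/mL).

    Specific uptake is growth-coupled: Q_i = mu / Y_i (mM per cell per h).
    """
    if params.Y_Glu <= 0 or params.Y_Glc <= 0:
        raise ValueError("yields Y_Glu and Y_Glc must be positive")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    cells_per_L = X_V * CELLS_PER_ML_TO_PER_L
    Q_Glu = mu / params.Y_Glu
    Q_Glc = mu / params.Y_Glc
    return -Q_Glu * cells_per_L, -Q_Glc * cells_per_L


def lactate_rate(
    mu: float,
    X_V: float,
    substrates: SubstrateState,
    params: ModelParameters,
) -> float:
    """dLac/dt (mM/h): produced from glucose and glutamate consumption,
    consumed once glutamate is depleted.

    Production couples to the substrate uptake rates with yield ``Y_Lac``
    (half stoichiometry on the glutamate route).  Consumption ``Q_Lac`` is a
    per-cell rate switched on by glutamate depletion via ``1 - f_limGlu``.
    """
    f_glu, _, _ = limiting_factors(substrates, params)
    dGlu, dGlc = substrate_rates(mu, X_V, params)
    Q_Glu_cells, Q_Glc_cells = -dGlu, -dGlc  # uptake rates, mM/h, >= 0
    production = Q_Glc_cells * params.Y_Lac * f_glu + Q_Glu_cells * params.Y_Lac / 2.0
    consumption = params.Q_Lac * (1.0 - f_glu) * X_V * CELLS_PER_ML_TO_PER_L
    return production - consumption


def mab_rate(
    f_G1: float,
    f_S: float,
    f_G2: float,
    X_V: float,
    params: ModelParameters,
    tol: float = 1e-6,
) -> float:
    """dmAb/dt (mg/L/h) from cell-cycle-phase-weighted specific productivity."""
    if X_V > 0 and abs(f_G1 + f_S + f_G2 - 1.0) > tol:
        raise ValueError("cell cycle fractions must sum to 1")
    q = params.q_G1 * f_G1 + params.q_S * f_S + params.q_G2 * f_G2
    return q * X_V * CELLS_PER_ML_TO_PER_L


def dead_cell_rate(
    k_d: float, X_V: float, X_D: float, params: ModelParameters
) -> float:
    """dX_D/dt (cells/mL/h): death of viable cells minus lysis of dead cells."""
    if X_V < 0 or X_D < 0:
        raise ValueError("cell densities must be >= 0")
    return k_d * X_V - params.k_lys * X_D


def viability(X_V: float, X_D: float) -> float:
    """Viable fraction X_V / (X_V + X_D); 1.0 for an empty culture."""
    total = X_V + X_D
    if total <= 0:
        return 1.0
    return X_V / total
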