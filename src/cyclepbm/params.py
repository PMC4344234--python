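"""Model parameter registry, validation and bundled presets.

The registry holds the 24 kinetic/metabolic parameters that are subject to
sensitivity analysis and estimation, plus the domain geometry (cyclin/DNA
domain bounds, bin counts) and the cyclin B1 level at which S-phase leavers
are deposited into the G2/M domain.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, fields
from typing import Any, Mapping

__all__ = [
    "ModelParameters",
    "GSA_PARAMETER_NAMES",
    "NOMINAL",
    "ESTIMATED",
    "DMSO_DELAY_OVERRIDES",
    "load_preset",
]


#: Names of the 24 registered kinetic/metabolic parameters, in registry order.
#: Domain geometry (cycEmax, cycBmin, cycBmax, bin counts, deposition level)
#: is deliberately excluded: it defines the numerical domain, not the model
#: physics, and is never sampled or estimated.
GSA_PARAMETER_NAMES: tuple[str, ...] = (
    "critE_threshold",
    "critB_threshold",
    "prob_G1",
    "prob_G2",
    "CycEgrow",
    "DNAgrow",
    "CycBgrow",
    "k_dmax",
    "k_lys",
    "K_Lac",
    "Q_Lac",
    "k_dGlu",
    "Y_Glc",
    "K_Glc",
    "Y_Glu",
    "K_Glu",
    "Y_Lac",
    "q_G1",
    "q_S",
    "q_G2",
    "m_expglc",
    "n_expglu",
    "q_expdeath",
    "p_explac",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set: 24 registered parameters + domain geometry.

    Units follow the nomenclature of the source system: cyclin contents are
    percent-of-maximum fluorescence, DNA is relative content on [1, 2],
    substrate concentrations are mM, cell densities cells/mL, antibody mg/L.
    Yields ``Y_Glu``/``Y_Glc`` are cells produced per litre of culture per mM
    of substrate consumed; specific productivities ``q_*`` are mg per cell
    per hour.
    """

    # -- thresholds and transition magnitudes -------------------------------
    critE_threshold: float = 15.0      # % cyc E
    critB_threshold: float = 37.0      # % cyc B
    prob_G1: float = 0.6               # 1/h
    prob_G2: float = 0.6               # 1/h
    # -- growth rates -------------------------------------------------------
    CycEgrow: float = 3.33             # % cyc E / h
    DNAgrow: float = 0.15              # DNA / h
    CycBgrow: float = 8.22             # % cyc B / h
    # -- death / lysis ------------------------------------------------------
    k_dmax: float = 3.0e-2             # 1/h
    k_lys: float = 5.0e-3              # 1/h
    k_dGlu: float = 0.05               # mM
    # -- Monod constants, yields, consumption -------------------------------
    K_Lac: float = 50.0                # mM
    Q_Lac: float = 2.5e-11             # mM per cell per h (specific consumption)
    Y_Glc: float = 2.1e8               # cell/mM
    K_Glc: float = 5.0                 # mM
    Y_Glu: float = 1.8e9               # cell/mM
    K_Glu: float = 0.20                # mM
    Y_Lac: float = 2.3                 # dimensionless
    # -- phase-specific productivities --------------------------------------
    q_G1: float = 5.0e-10              # mg/(cell h)
    q_S: float = 5.0e-10               # mg/(cell h)
    q_G2: float = 5.0e-10              # mg/(cell h)
    # -- Monod exponents ----------------------------------------------------
    m_expglc: float = 2.0
    n_expglu: float = 1.0
    q_expdeath: float = 2.0
    p_explac: float = 1.0
    # -- domain geometry (not registered for GSA/estimation) ----------------
    cycEmax: float = 95.0              # % cyc E
    cycBmin: float = 0.0               # % cyc B
    cycBmax: float = 95.0              # % cyc B
    nE: int = 200
    nDNA: int = 20
    nB: int = 200
    cycB_S_G2M: float = 15.0           # % cyc B deposited on S -> G2/M transit

    def __post_init__(self) -> None:
        for name in GSA_PARAMETER_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {value}")
        if not 0.0 <= self.critE_threshold <= self.cycEmax:
            raise ValueError("critE_threshold must lie within [0, cycEmax]")
        if self.cycBmax <= self.cycBmin:
            raise ValueError("cycBmax must exceed cycBmin")
        if not self.cycBmin <= self.critB_threshold <= self.cycBmax:
            raise ValueError("critB_threshold must lie within [cycBmin, cycBmax]")
        if not self.cycBmin <= self.cycB_S_G2M <= self.cycBmax:
            raise ValueError("cycB_S_G2M must lie within [cycBmin, cycBmax]")
        for name in ("nE", "nDNA", "nB"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.cycEmax <= 0:
            raise ValueError("cycEmax must be positive")

    # -- convenience --------------------------------------------------------
    def replace(self, **overrides: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **overrides)

    def registered_values(self) -> dict[str, float]:
        """The 24 registered parameters as an ordered name -> value mapping."""
        return {name: getattr(self, name) for name in GSA_PARAMETER_NAMES}

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))


#: Nominal parameter values (defaults of :class:`ModelParameters`).
NOMINAL = ModelParameters()

#: Re-estimated values for the significant parameter subset; all other
#: parameters keep their nominal value.
ESTIMATED = NOMINAL.replace(
    CycEgrow=3.49,
    DNAgrow=0.16,
    CycBgrow=8.07,
    k_dmax=2.31e-2,
    Y_Glu=1.80e9,
    q_G1=9.57e-10,
    q_S=1.00e-10,
    q_G2=1.00e-11,
    q_expdeath=2.0,
)

#: Parameter overrides used during the first 24 h of a DMSO arrest-release
#: simulation (slowed G1 progression and matching yield adjustment).
DMSO_DELAY_OVERRIDES: dict[str, float] = {
    "CycEgrow": 1.52,
    "Y_Glc": 9.1e7,
    "Y_Glu": 7.4e8,
}

#: 95% confidence half-widths reported alongside the estimated preset.
ESTIMATED_CONFIDENCE: dict[str, float] = {
    "CycEgrow": 1.46e-1,
    "DNAgrow": 4.76e-3,
    "CycBgrow": 2.99e-1,
    "k_dmax": 1.90e-3,
    "Y_Glu": 7.20e7,
    "q_G1": 2.10e-9,
    "q_S": 4.30e-9,
    "q_G2": 2.00e-9,
}

_PRESETS: dict[str, ModelParameters] = {
    "table2_nominal": NOMINAL,
    "table2_estimated": ESTIMATED,
}


def load_preset(name: str) -> ModelParameters:
    """Load a bundled parameter preset ("table2_nominal" or "table2_estimated")."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
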