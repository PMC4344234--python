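"""Pure rate laws: Monod limiting functions, growth/transition/death rates.

All operations are stateless functions of a :class:`SubstrateState` and a
:class:`~cyclepbm.params.ModelParameters` instance.  Content arguments are
accepted as scalars or numpy arrays; array inputs return arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from cyclepbm.params import ModelParameters

__all__ = [
    "SubstrateState",
    "limiting_factors",
    "cyclin_growth_rate",
    "dna_growth_rate",
    "transition_rate",
    "specific_death_rate",
    "phase_times_and_growth_rate",
    "doubling_time",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class SubstrateState:
    """Extracellular substrate/metabolite concentrations (mM)."""

    Glu: float
    Glc: float
    Lac: float

    def __post_init__(self) -> None:
        for name in ("Glu", "Glc", "Lac"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def _monod(s: float, K: float, exponent: float) -> float:
    # s^n / (s^n + K^n), safe at s = 0 for any n >= 0
    if K <= 0:
        raise ValueError(f"Monod constant must be positive, got {K}")
    if s == 0.0 and exponent > 0:
        return 0.0
    sn = s**exponent
    return sn / (sn + K**exponent)


def limiting_factors(
    substrates: SubstrateState, params: ModelParameters
) -> tuple[float, float, float]:
    """Dimensionless Monod limiting factors (f_limGlu, f_limGlc, f_limLac).

    Glutamate and glucose act as saturating stimulators; lactate acts as an
    inhibitor (its factor decreases from 1 as lactate accumulates).
    """
    f_glu = _monod(substrates.Glu, params.K_Glu, params.n_expglu)
    f_glc = _monod(substrates.Glc, params.K_Glc, params.m_expglc)
    f_lac = 1.0 - _monod(substrates.Lac, params.K_Lac, params.p_explac)
    return f_glu, f_glc, f_lac


def cyclin_growth_rate(
    phase: str, substrates: SubstrateState, params: ModelParameters
) -> float:
    """Cyclin build-up rate (% cyclin/h) for phase "G1" (cyclin E1) or "G2" (cyclin B1).

    Glutamate-stimulated and lactate-inhibited.
    """
    f_glu, _, f_lac = limiting_factors(substrates, params)
    if phase == "G1":
        base = params.CycEgrow
    elif phase == "G2":
        base = params.CycBgrow
    else:
        raise ValueError(f"unknown phase {phase!r}; expected 'G1' or 'G2'")
    return base * f_glu * f_lac


def dna_growth_rate(substrates: SubstrateState, params: ModelParameters) -> float:
    """DNA synthesis rate (DNA/h); glutamate-limited only (no lactate term)."""
    f_glu, _, _ = limiting_factors(substrates, params)
    return params.DNAgrow * f_glu


def transition_rate(
    content: ArrayLike,
    phase: str,
    substrates: SubstrateState,
    params: ModelParameters,
) -> ArrayLike:
    """Phase-exit transition rate (1/h) as a step function of cyclin content.

    Zero below the phase's cyclin threshold; ``prob_i * f_limGlc`` at or above
    it (the threshold itself is inclusive, so the discrete node holding the
    threshold is active).
    """
    _, f_glc, _ = limiting_factors(substrates, params)
    if phase == "G1":
        lo, hi = 0.0, params.cycEmax
        threshold, magnitude = params.critE_threshold, params.prob_G1
    elif phase == "G2":
        lo, hi = params.cycBmin, params.cycBmax
        threshold, magnitude = params.critB_threshold, params.prob_G2
    else:
        raise ValueError(f"unknown phase {phase!r}; expected 'G1' or 'G2'")
    content_arr = np.asarray(content, dtype=float)
    if np.any(content_arr < lo) or np.any(content_arr > hi):
        raise ValueError(f"content outside the {phase} domain [{lo}, {hi}]")
    rate = np.where(content_arr >= threshold, magnitude * f_glc, 0.0)
    return float(rate) if np.isscalar(content) else rate


def specific_death_rate(Glu: float, params: ModelParameters) -> float:
    """Specific death rate k_d (1/h); saturates at k_dmax as glutamate depletes."""
    if Glu < 0:
        raise ValueError("Glu must be >= 0")
    if params.k_dGlu <= 0:
        return params.k_dmax if Glu == 0 else 0.0
    return params.k_dmax * (params.k_dGlu / (params.k_dGlu + Glu)) ** params.q_expdeath


def phase_times_and_growth_rate(
    substrates: SubstrateState, params: ModelParameters
) -> tuple[float, float, float, float]:
    """Minimum phase transit times (h) and specific growth rate mu (1/h).

    t_G1 and t_G2 are the times to build cyclin up to the respective
    transition threshold; t_S is the time to double DNA content (one full
    unit of relative DNA).  mu = ln(2) / (t_G1 + t_S + t_G2).  When any
    growth rate vanishes (substrate depletion) the affected transit time is
    infinite and mu is 0 — growth is arrested, not an error.
    """
    r_G1 = cyclin_growth_rate("G1", substrates, params)
    r_S = dna_growth_rate(substrates, params)
    r_G2 = cyclin_growth_rate("G2", substrates, params)
    if r_G1 <= 0.0 or r_S <= 0.0 or r_G2 <= 0.0:
        t_G1 = params.critE_threshold / r_G1 if r_G1 > 0 else math.inf
        t_S = 1.0 / r_S if r_S > 0 else math.inf
        t_G2 = params.critB_threshold / r_G2 if r_G2 > 0 else math.inf
        return t_G1, t_S, t_G2, 0.0
    t_G1 = params.critE_threshold / r_G1
    t_S = 1.0 / r_S
    t_G2 = params.critB_threshold / r_G2
    mu = math.log(2.0) / (t_G1 + t_S + t_G2)
    return t_G1, t_S, t_G2, mu


def doubling_time(mu: float) -> float:
    """Population doubling time ln(2)/mu (h); infinite for mu <= 0."""
    if mu <= 0:
        return math.inf
    return math.log(2.0) / mu
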