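"""Entities-conservation pre-test and variance-based global sensitivity analysis.

The sensitivity workflow samples all 24 registered parameters uniformly
within a ±fraction band around their nominal values using a Sobol
low-discrepancy sequence, simulates a batch scenario per sample, and
estimates first-order variance-based sensitivity indices (SIs) for each
(output, time) pair with a random-sampling HDMR surrogate: each parameter's
first-order component function is expanded in orthonormal shifted Legendre
polynomials whose coefficients are Monte-Carlo projections of the output on
the sample.  A parameter is significant when any of its SIs exceeds the
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import eval_sh_legendre
from scipy.stats import qmc

from cyclepbm.fixtures import (
    ScenarioSpec,
    default_batch_scenario,
    uniform_population,
)
from cyclepbm.metabolic import CultureState
from cyclepbm.params import GSA_PARAMETER_NAMES, ModelParameters
from cyclepbm.pbm import build_grids
from cyclepbm.simulator import SimulationConfig, simulate
from cyclepbm.fixtures import build_initial_state, CHANNEL_COLUMNS

__all__ = [
    "GSAConfig",
    "GSAResult",
    "conservation_test",
    "sample_parameters",
    "first_order_indices",
    "classify_significant",
    "run_gsa",
]

#: Default outputs and evaluation times of the screening study.
DEFAULT_OUTPUTS = ("X_V", "f_G1", "f_S", "f_G2", "mAb")
DEFAULT_TIMES = (36.0, 72.0, 120.0)


@dataclass(frozen=True)
class GSAConfig:
    """Configuration of the screening study."""

    variation: float = 0.5                 # ± fraction around nominal
    n_samples: int = 4096
    seed: int = 0
    outputs: tuple[str, ...] = DEFAULT_OUTPUTS
    times: tuple[float, ...] = DEFAULT_TIMES
    threshold: float = 0.1
    polynomial_order: int = 3
    parameters: tuple[str, ...] = GSA_PARAMETER_NAMES

    def __post_init__(self) -> None:
        if not 0 <= self.variation < 1:
            raise ValueError("variation must be in [0, 1)")
        if self.n_samples < 8:
            raise ValueError("n_samples too small for SI estimation")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        unknown = set(self.outputs) - set(CHANNEL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown outputs: {sorted(unknown)}")


@dataclass
class GSAResult:
    """SI table (parameter x (output, time)) and derived significance calls."""

    indices: pd.DataFrame
    threshold: float
    n_evaluated: int
    n_failed: int

    @property
    def significant(self) -> list[str]:
        mask = (self.indices > self.threshold).any(axis=1)
        return sorted(self.indices.index[mask])

    def to_long_frame(self) -> pd.DataFrame:
        long = self.indices.stack([0, 1], future_stack=True).reset_index()
        long.columns = ["parameter", "output", "time_h", "SI"]
        return long


def conservation_test(
    params: ModelParameters,
    bins: tuple[int, int, int] | None = None,
    horizon_h: float = 120.0,
) -> float:
    """Fraction of entities retained after ``horizon_h`` hours.

    Runs the simulator in conservation mode: division birth factor 1 (no
    generation), zero death rate, all Monod limiting factors pinned to 1 and
    uniform initial densities over the three full domains.
    """
    if bins is not None:
        nE, nDNA, nB = bins
        params = params.replace(nE=nE, nDNA=nDNA, nB=nB)
    params = params.replace(k_dmax=0.0)
    if horizon_h == 0:
        return 1.0
    grid = build_grids(params)
    pop = uniform_population(grid, 1.0e6)
    config = SimulationConfig(
        t_end=horizon_h,
        report_times=[0.0, horizon_h],
        birth_factor=1,
        pin_limiting=True,
        cfl_safety=0.95,
    )
    traj = simulate(pop, CultureState(), params, config)
    return float(traj["total"][-1] / traj["total"][0])


def sample_parameters(
    config: GSAConfig, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Sobol-sequence scenario matrix.

    Returns ``(unit, scaled)``: ``unit`` holds the raw points in [0, 1)^d,
    ``scaled`` the parameter values mapped to nominal*(1 ± variation).
    Deterministic for a fixed seed.
    """
    names = config.parameters
    d = len(names)
    sampler = qmc.Sobol(d=d, scramble=True, seed=config.seed)
    unit = sampler.random(config.n_samples)
    nominal = np.array([getattr(params, name) for name in names])
    lo = nominal * (1.0 - config.variation)
    hi = nominal * (1.0 + config.variation)
    scaled = lo + unit * (hi - lo)
    return unit, scaled


def _orthonormal_legendre(unit: np.ndarray, order: int) -> np.ndarray:
    """phi_j(u) for j = 1..order, orthonormal on U[0, 1]; shape (order, n, d)."""
    basis = np.empty((order, *unit.shape))
    for j in range(1, order + 1):
        basis[j - 1] = math.sqrt(2 * j + 1) * eval_sh_legendre(j, unit)
    return basis


def first_order_indices(
    unit_samples: np.ndarray,
    outputs: np.ndarray,
    order: int = 3,
) -> np.ndarray:
    """First-order variance-based SIs via RS-HDMR polynomial projection.

    ``unit_samples``: (n, d) points in [0, 1]; ``outputs``: (n,) or (n, m).
    Returns (d,) or (d, m) indices clipped to [0, 1].  Rows with non-finite
    outputs must be removed by the caller.
    """
    unit_samples = np.asarray(unit_samples, dtype=float)
    y = np.asarray(outputs, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if len(y) != len(unit_samples):
        raise ValueError("outputs and samples must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("outputs must be finite")
    yc = y - y.mean(axis=0)
    var = yc.var(axis=0)
    basis = _orthonormal_legendre(unit_samples, order)  # (order, n, d)
    # alpha[j, d, m]: Monte-Carlo projection of y on phi_j(u_d)
    alpha = np.einsum("jnd,nm->jdm", basis, yc) / len(y)
    component_var = np.sum(alpha**2, axis=0)  # (d, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        si = component_var / var[None, :]
    si[:, var == 0] = 0.0  # degenerate zero-variance output
    si = np.clip(si, 0.0, 1.0)
    return si[:, 0] if squeeze else si


def classify_significant(
    indices: pd.DataFrame | np.ndarray,
    threshold: float,
    names: Sequence[str] | None = None,
) -> list[str]:
    """Parameters whose SI exceeds ``threshold`` for any output/time."""
    if isinstance(indices, pd.DataFrame):
        arr = indices.to_numpy()
        names = list(indices.index)
    else:
        arr = np.atleast_2d(np.asarray(indices, dtype=float).T).T
        if names is None:
            raise ValueError("names required for array input")
    mask = (arr > threshold).any(axis=1)
    return sorted(str(n) for n, m in zip(names, mask) if m)


def _evaluate_scenario(
    values: np.ndarray,
    base: ModelParameters,
    scenario: ScenarioSpec,
    config: GSAConfig,
    sim_config: SimulationConfig,
) -> np.ndarray | None:
    overrides = dict(zip(config.parameters, values))
    try:
        params = base.replace(**overrides)
        grid = build_grids(params)
        pop, culture = build_initial_state(scenario, params, grid)
        traj = simulate(pop, culture, params, sim_config)
    except Exception:
        return None
    row = np.empty(len(config.outputs) * len(config.times))
    i = 0
    for output in config.outputs:
        column = CHANNEL_COLUMNS[output]
        for t in config.times:
            row[i] = traj.at(t, column)
            i += 1
    return row if np.all(np.isfinite(row)) else None


def run_gsa(
    params: ModelParameters,
    config: GSAConfig | None = None,
    scenario: ScenarioSpec | None = None,
    sim_config: SimulationConfig | None = None,
) -> GSAResult:
    """Full screening pipeline: sample, simulate, estimate SIs, classify."""
    config = config or GSAConfig()
    scenario = scenario or default_batch_scenario()
    if sim_config is None:
        t_end = max(config.times)
        sim_config = SimulationConfig(t_end=t_end, report_times=sorted({0.0, *config.times}))
    unit, scaled = sample_parameters(config, params)
    rows: list[np.ndarray] = []
    keep: list[int] = []
    for idx, values in enumerate(scaled):
        row = _evaluate_scenario(values, params, scenario, config, sim_config)
        if row is not None:
            rows.append(row)
            keep.append(idx)
    n_failed = len(scaled) - len(rows)
    if len(rows) < 8:
        raise RuntimeError(f"too few successful simulations ({len(rows)})")
    outputs = np.vstack(rows)
    si = first_order_indices(unit[keep], outputs, order=config.polynomial_order)
    columns = pd.MultiIndex.from_tuples(
        [(o, t) for o in config.outputs for t in config.times],
        names=["output", "time_h"],
    )
    table = pd.DataFrame(si, index=list(config.parameters), columns=columns)
    return GSAResult(
        indices=table,
        threshold=config.threshold,
        n_evaluated=len(rows),
        n_failed=n_failed,
    )
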