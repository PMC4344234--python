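"""Scenario builders and synthetic observation generation.

Everything needed to exercise the simulator, sensitivity analysis and
estimation without external data: uniform and arrest-release initial
population distributions, default batch scenarios and a noisy synthetic
observation generator for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cyclepbm.metabolic import CultureState
from cyclepbm.params import ModelParameters
from cyclepbm.pbm import DomainGrid, PopulationState, aggregate
from cyclepbm.simulator import ScheduleWindow, SimulationConfig, Trajectory, simulate

__all__ = [
    "ScenarioSpec",
    "NoiseModel",
    "ObservationSet",
    "uniform_population",
    "arrested_population",
    "population_from_fractions",
    "build_initial_state",
    "synthesize_observations",
    "default_batch_scenario",
    "conservation_scenario",
]

#: Channels a trajectory can be observed on, mapped to trajectory columns.
CHANNEL_COLUMNS: dict[str, str] = {
    "X_V": "Xv",
    "viability": "viability",
    "Glu": "Glu_mM",
    "Glc": "Glc_mM",
    "Lac": "Lac_mM",
    "mAb": "mAb_mgL",
    "f_G1": "fG1",
    "f_S": "fS",
    "f_G2": "fG2",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully-specified batch scenario."""

    name: str
    total_cells: float
    fractions: tuple[float, float, float] = (1.0 / 3, 1.0 / 3, 1.0 / 3)
    shape: str = "uniform_subthreshold"  # or uniform_full, pulse, thymidine, dmso
    culture: CultureState = field(default_factory=CultureState)
    schedule: tuple[ScheduleWindow, ...] = ()

    def __post_init__(self) -> None:
        if self.total_cells < 0:
            raise ValueError("total_cells must be >= 0")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, per channel."""

    relative_sd: Mapping[str, float] = field(default_factory=dict)
    default_sd: float = 0.05
    seed: int = 0

    def sd_for(self, channel: str) -> float:
        sd = float(self.relative_sd.get(channel, self.default_sd))
        if sd < 0:
            raise ValueError("relative SDs must be >= 0")
        return sd


@dataclass
class ObservationSet:
    """Observed time series with per-channel SDs plus replay information."""

    times: np.ndarray
    values: dict[str, np.ndarray]
    sigmas: dict[str, np.ndarray]
    scenario: ScenarioSpec
    truth_params: ModelParameters | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("observation times must be sorted")
        if not self.values:
            raise ValueError("at least one observation channel is required")
        for name, vals in self.values.items():
            if name not in CHANNEL_COLUMNS:
                raise ValueError(f"unknown channel {name!r}")
            if len(vals) != len(self.times):
                raise ValueError(f"channel {name!r} length mismatch")
            if np.any(self.sigmas[name] <= 0):
                raise ValueError("observation SDs must be > 0")

    @property
    def channels(self) -> list[str]:
        return list(self.values)


def _block_density(
    nodes: np.ndarray, lo: float, hi: float, mass: float, h: float
) -> np.ndarray:
    """Constant density on nodes with coordinate in [lo, hi], scaled so the
    aggregation quadrature (h * sum) over the domain equals ``mass`` exactly."""
    density = np.where((nodes >= lo - 1e-12) & (nodes <= hi + 1e-12), 1.0, 0.0)
    integral = h * float(np.sum(density))
    if integral <= 0:
        # degenerate window: put everything on the nearest node to lo
        density = np.zeros_like(nodes)
        idx = int(np.argmin(np.abs(nodes - lo)))
        density[idx] = 1.0
        integral = h
    return density * (mass / integral)


def uniform_population(grid: DomainGrid, total: float) -> PopulationState:
    """Equal density on every node of all three domains, normalized to ``total``."""
    if total < 0:
        raise ValueError("total must be >= 0")
    length = (
        grid.hE * (grid.nE + 1)
        + grid.hDNA * (grid.nDNA + 1)
        + grid.hB * (grid.nB + 1)
    )
    c = total / length if length > 0 else 0.0
    return PopulationState(
        N_E=np.full(grid.nE + 1, c),
        N_DNA=np.full(grid.nDNA + 1, c),
        N_B=np.full(grid.nB + 1, c),
    )


def population_from_fractions(
    grid: DomainGrid,
    params: ModelParameters,
    total: float,
    fractions: Sequence[float],
    shape: str = "uniform_subthreshold",
) -> PopulationState:
    """Distribute ``total`` cells over the three domains with per-phase masses
    given by ``fractions`` and a within-domain placement given by ``shape``."""
    f_G1, f_S, f_G2 = fractions
    if abs(f_G1 + f_S + f_G2 - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    e_lo, e_hi = float(grid.nodes_E[0]), float(grid.nodes_E[-1])
    d_lo, d_hi = float(grid.nodes_DNA[0]), float(grid.nodes_DNA[-1])
    b_lo, b_hi = float(grid.nodes_B[0]), float(grid.nodes_B[-1])

    if shape == "uniform_full":
        e_win, d_win, b_win = (e_lo, e_hi), (d_lo, d_hi), (b_lo, b_hi)
    elif shape == "uniform_subthreshold":
        e_win = (e_lo, params.critE_threshold)
        d_win = (d_lo, d_hi)
        b_win = (b_lo, params.critB_threshold)
    elif shape == "pulse":
        # narrow packets near the bottom of each domain, for advection tests
        e_win = (e_lo, e_lo + 5 * grid.hE)
        d_win = (d_lo, d_lo + 3 * grid.hDNA)
        b_win = (b_lo, b_lo + 5 * grid.hB)
    elif shape == "thymidine":
        # arrest at the G1/S boundary: G1 mass piled just under the cyclin E1
        # threshold, S mass in early-S (low DNA) nodes
        e_win = (0.8 * params.critE_threshold, params.critE_threshold)
        d_win = (d_lo, d_lo + 0.3 * (d_hi - d_lo))
        b_win = (b_lo, params.critB_threshold)
    elif shape == "dmso":
        # G1 arrest: mass held at low, sub-threshold cyclin E1 content
        e_win = (e_lo, 0.5 * params.critE_threshold)
        d_win = (d_lo, d_lo + 0.5 * (d_hi - d_lo))
        b_win = (b_lo, params.critB_threshold)
    else:
        raise ValueError(f"unknown within-domain shape {shape!r}")

    return PopulationState(
        N_E=_block_density(grid.nodes_E, *e_win, total * f_G1, grid.hE),
        N_DNA=_block_density(grid.nodes_DNA, *d_win, total * f_S, grid.hDNA),
        N_B=_block_density(grid.nodes_B, *b_win, total * f_G2, grid.hB),
    )


def arrested_population(
    grid: DomainGrid,
    mode: str,
    total: float,
    fractions: Sequence[float],
    params: ModelParameters | None = None,
) -> PopulationState:
    """Arrest-release initial distribution ("thymidine" or "dmso")."""
    if mode not in ("thymidine", "dmso"):
        raise ValueError("mode must be 'thymidine' or 'dmso'")
    params = params or ModelParameters()
    return population_from_fractions(grid, params, total, fractions, shape=mode)


def build_initial_state(
    scenario: ScenarioSpec, params: ModelParameters, grid: DomainGrid
) -> tuple[PopulationState, CultureState]:
    """Materialize a scenario's initial population and culture state."""
    if scenario.shape == "uniform_full" and scenario.fractions == (1.0 / 3, 1.0 / 3, 1.0 / 3):
        pop = uniform_population(grid, scenario.total_cells)
    else:
        pop = population_from_fractions(
            grid, params, scenario.total_cells, scenario.fractions, scenario.shape
        )
    return pop, dataclasses.replace(scenario.culture)


def default_batch_scenario(
    name: str = "batch_control",
    X_V0: float = 4.0e5,
    V: float = 100.0,
    Glu0: float = 1.5,
    Glc0: float = 25.0,
    fractions: tuple[float, float, float] = (0.55, 0.25, 0.20),
    shape: str = "uniform_subthreshold",
    schedule: tuple[ScheduleWindow, ...] = (),
) -> ScenarioSpec:
    """A plausible batch inoculation (package convention, not literature data).

    The defaults are chosen so a nominal-parameter run reproduces the broad
    shape of a 5-day batch: exponential growth to a few 1e6 cells/mL,
    glutamate exhaustion around day 3 followed by viability decline, and a
    lactate peak of a few tens of mM that is consumed after the glutamate
    runs out.
    """
    return ScenarioSpec(
        name=name,
        total_cells=X_V0 * V,
        fractions=fractions,
        shape=shape,
        culture=CultureState(Glu=Glu0, Glc=Glc0, Lac=0.0, mAb=0.0, X_D=0.0, V=V),
        schedule=schedule,
    )


def conservation_scenario(total: float = 1.0e6, V: float = 100.0) -> ScenarioSpec:
    """Uniform distributions over all three full domains (entities test)."""
    return ScenarioSpec(
        name="conservation",
        total_cells=total,
        fractions=(1.0 / 3, 1.0 / 3, 1.0 / 3),
        shape="uniform_full",
        culture=CultureState(Glu=4.0, Glc=25.0, Lac=0.0, mAb=0.0, X_D=0.0, V=V),
    )


def simulate_scenario(
    scenario: ScenarioSpec,
    params: ModelParameters,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Convenience wrapper: build the initial state and run the simulator."""
    from cyclepbm.pbm import build_grids

    grid = build_grids(params)
    pop, culture = build_initial_state(scenario, params, grid)
    if config is None:
        config = SimulationConfig(schedule=scenario.schedule)
    elif not config.schedule and scenario.schedule:
        config = dataclasses.replace(config, schedule=scenario.schedule)
    return simulate(pop, culture, params, config)


def synthesize_observations(
    params: ModelParameters,
    scenario: ScenarioSpec,
    sample_times: Sequence[float],
    noise: NoiseModel,
    channels: Sequence[str] = ("X_V", "viability", "Glu", "Glc", "Lac", "mAb", "f_G1", "f_S", "f_G2"),
    config: SimulationConfig | None = None,
) -> ObservationSet:
    """Simulate the scenario and sample noisy observations on it.

    Noise is multiplicative Gaussian per channel: obs = truth * (1 + sd * z).
    Negative draws are clipped at zero.  The truth parameter set is recorded
    on the result for recovery tests.
    """
    sample_times = np.asarray(sorted(float(t) for t in sample_times))
    if config is None:
        t_end = float(sample_times[-1]) if len(sample_times) else 0.0
        config = SimulationConfig(t_end=t_end, report_times=sample_times, schedule=scenario.schedule)
    traj = simulate_scenario(scenario, params, config)
    rng = np.random.default_rng(noise.seed)
    values: dict[str, np.ndarray] = {}
    sigmas: dict[str, np.ndarray] = {}
    for channel in channels:
        column = CHANNEL_COLUMNS[channel]
        truth = np.array([traj.at(t, column) for t in sample_times])
        sd = noise.sd_for(channel)
        draw = truth * (1.0 + sd * rng.standard_normal(len(sample_times)))
        values[channel] = np.maximum(draw, 0.0)
        # absolute SDs for weighting; floor keeps zero-valued channels usable
        scale = max(float(np.max(np.abs(truth))), 1e-12)
        sigmas[channel] = np.maximum(sd * np.abs(truth), 1e-3 * scale) if sd > 0 else np.full(
            len(sample_times), 1e-3 * scale
        )
    return ObservationSet(
        times=sample_times,
        values=values,
        sigmas=sigmas,
        scenario=scenario,
        truth_params=params,
    )
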