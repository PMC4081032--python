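"""Stochastic annual fire model: climate- and fuel-driven flammability,
random ignition, cellular-automata spread, spin-up, replicate ensembles.

Per-cell flammability is a probability-like coefficient

    f = clamp01( logistic(b0 + bT*T + bP*P) * veg_scalar[veg] * fuel(age) )

with ``fuel(age) = min(1, age / A_fuel)`` realising fuel build-up through
succession (a fresh burn carries no fuel).  Each cell ignites in a year iff
an independent uniform draw falls below ``f``.  A fire spreads as a
breadth-first front on the 8-neighbourhood: every burning cell attempts
each not-yet-burned neighbour once, igniting it with probability
``clamp01(spread_factor * f(neighbour))``.

The published regression behind the climate-flammability link is not
reproduced here; the logistic parameterisation preserves its stated
dependencies (climate, vegetation state, time since fire) with bounded
output, and every coefficient is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .succession import SuccessionParams, apply_transitions
from .types import ClimateCube, FireEvent, LandscapeState, RunEnsemble, VegClass

__all__ = [
    "FlammabilityParams",
    "BaselineClimateSampler",
    "flammability_map",
    "ignite",
    "spread_fire",
    "step_year",
    "spin_up",
    "run_ensemble",
]

_DEFAULT_VEG_SCALAR = {
    VegClass.ROCK_ICE: 0.0,
    VegClass.TUNDRA: 0.25,   # tundra burns rarely relative to boreal conifer
    VegClass.BLACK_SPRUCE: 1.0,
    VegClass.WHITE_SPRUCE: 0.9,
    VegClass.DECIDUOUS: 0.6,
}

# offsets of the 8-neighbourhood, row-major order
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FlammabilityParams:
    """Coefficients of the flammability model and spread mechanics.

    Defaults are tuned to a boreal-like baseline regime on the synthetic
    climate (growing season ~11 °C, ~300 mm): mature black spruce ignites
    with probability ~1e-3 per pixel-year and neighbour spread probability
    ~0.2, giving roughly a 1%/yr landscape burn rate (fire rotation on the
    order of a century) at baseline and a super-linear response to the
    multi-degree warming of the hot trajectory.
    """

    beta0: float = -7.3
    beta_t: float = 0.09   # per °C
    beta_p: float = -0.002  # per mm (wetter growing seasons damp fire)
    veg_scalar: dict[VegClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_VEG_SCALAR)
    )
    fuel_age_scale: float = 30.0  # years to full fuel load
    spread_factor: float = 220.0
    max_ignitions_per_year: int | None = None

    def __post_init__(self) -> None:
        self.veg_scalar = {VegClass(k): float(v) for k, v in self.veg_scalar.items()}
        for c in VegClass:
            self.veg_scalar.setdefault(c, 0.0)
        if self.veg_scalar[VegClass.ROCK_ICE] != 0.0:
            raise ValueError("rock/ice flammability scalar is fixed at 0")
        if self.veg_scalar[VegClass.TUNDRA] > self.veg_scalar[VegClass.BLACK_SPRUCE]:
            raise ValueError("tundra must not be more flammable than black spruce")
        if any(not 0.0 <= v <= 1.0 for v in self.veg_scalar.values()):
            raise ValueError("vegetation scalars must lie in [0, 1]")
        if self.spread_factor < 0:
            raise ValueError("spread_factor must be >= 0")
        if self.fuel_age_scale < 0:
            raise ValueError("fuel_age_scale must be >= 0")

    def scalar_array(self) -> np.ndarray:
        return np.array([self.veg_scalar[c] for c in VegClass])


@dataclass
class BaselineClimateSampler:
    """Stationary baseline climate for spin-up: fixed means plus white noise."""

    t_mean: float = 11.0
    p_mean: float = 300.0
    noise_sd_t: float = 0.8
    noise_sd_p: float = 30.0

    def __call__(self, shape: tuple[int, int],
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        tas = np.full(shape, self.t_mean, dtype=float)
        pr = np.full(shape, self.p_mean, dtype=float)
        if self.noise_sd_t > 0:
            tas += rng.normal(0.0, self.noise_sd_t, size=shape)
        if self.noise_sd_p > 0:
            pr += rng.normal(0.0, self.noise_sd_p, size=shape)
        return tas, np.maximum(pr, 0.0)


def fuel_factor(age: np.ndarray, fuel_age_scale: float) -> np.ndarray:
    """Fuel build-up ramp min(1, age/A_fuel); A_fuel = 0 means always-full fuel."""
    age = np.maximum(age, 0)  # rock/ice sentinel handled by the veg scalar
    if fuel_age_scale <= 0:
        return np.ones_like(age, dtype=float)
    return np.minimum(1.0, age / float(fuel_age_scale))


def flammability_map(
    state: LandscapeState,
    climate_year: tuple[np.ndarray, np.ndarray],
    params: FlammabilityParams,
) -> np.ndarray:
    """Per-cell flammability coefficient in [0, 1]; rock/ice is 0."""
    tas, pr = climate_year
    tas = np.asarray(tas, dtype=float)
    pr = np.asarray(pr, dtype=float)
    if tas.shape != state.shape or pr.shape != state.shape:
        raise ValueError("climate grids must match the landscape shape")
    if np.isnan(tas).any() or np.isnan(pr).any():
        raise ValueError("climate fields contain NaN")
    climate = expit(params.beta0 + params.beta_t * tas + params.beta_p * pr)
    flam = climate * params.scalar_array()[state.veg] * fuel_factor(
        state.age, params.fuel_age_scale
    )
    return np.clip(flam, 0.0, 1.0)


def ignite(
    flam: np.ndarray,
    rng: np.random.Generator,
    max_ignitions: int | None = None,
) -> list[tuple[int, int]]:
    """Independent per-cell ignition draws against the flammability map.

    Each cell ignites iff a uniform draw falls below its flammability;
    when a cap is set, the successes are randomly subsampled down to it.
    """
    draws = rng.random(flam.shape)
    rows, cols = np.nonzero(draws < flam)
    cells = list(zip(rows.tolist(), cols.tolist()))
    if max_ignitions is not None and len(cells) > max_ignitions:
        idx = rng.choice(len(cells), size=max_ignitions, replace=False)
        cells = [cells[i] for i in sorted(idx)]
    return cells


def spread_fire(
    state: LandscapeState,
    flam: np.ndarray,
    ignition: tuple[int, int],
    params: FlammabilityParams,
    rng: np.random.Generator,
    blocked: np.ndarray | None = None,
) -> FireEvent:
    """Grow one fire from an ignition by breadth-first front spread.

    Each burning cell attempts each not-yet-burning 8-neighbour exactly
    once (one attempt per directed edge), igniting it with probability
    ``clamp01(spread_factor * flam(neighbour))``.  ``blocked`` marks cells
    already burned by an earlier fire this year; they cannot re-burn.
    Terminates when the front is empty.
    """
    r0, c0 = ignition
    if state.veg[r0, c0] == VegClass.ROCK_ICE:
        raise ValueError("cannot ignite a rock/ice pixel")
    if flam[r0, c0] <= 0:
        raise ValueError("ignition cell has zero flammability")
    n_rows, n_cols = state.shape
    spread_p = np.clip(params.spread_factor * flam, 0.0, 1.0)
    in_fire = np.zeros(state.shape, dtype=bool)
    in_fire[r0, c0] = True
    front = [(r0, c0)]
    cells = [(r0, c0)]
    while front:
        next_front: list[tuple[int, int]] = []
        for r, c in front:
            for dr, dc in _OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                if in_fire[rr, cc] or (blocked is not None and blocked[rr, cc]):
                    continue
                p = spread_p[rr, cc]
                if p > 0 and rng.random() < p:
                    in_fire[rr, cc] = True
                    next_front.append((rr, cc))
                    cells.append((rr, cc))
        front = next_front
    rows = np.array([r for r, _ in cells], dtype=np.int64)
    cols = np.array([c for _, c in cells], dtype=np.int64)
    return FireEvent(
        year=state.year + 1, ignition=ignition, rows=rows, cols=cols,
        pixel_area=state.pixel_area,
    )


def step_year(
    state: LandscapeState,
    climate_year: tuple[np.ndarray, np.ndarray],
    params: FlammabilityParams,
    succ_params: SuccessionParams,
    rng: np.random.Generator,
) -> tuple[LandscapeState, list[FireEvent], np.ndarray]:
    """Simulate one annual time step.

    Flammability -> ignition -> spread of each fire in RNG-shuffled order
    (cells burned by an earlier fire this year are excluded) -> succession
    transitions and aging.  Returns the next state (year advanced by one),
    the year's fires, and the union burn mask.
    """
    flam = flammability_map(state, climate_year, params)
    ignitions = ignite(flam, rng, params.max_ignitions_per_year)
    if len(ignitions) > 1:
        order = rng.permutation(len(ignitions))
        ignitions = [ignitions[i] for i in order]
    burned = np.zeros(state.shape, dtype=bool)
    fires: list[FireEvent] = []
    for cell in ignitions:
        if burned[cell]:
            continue
        fire = spread_fire(state, flam, cell, params, rng, blocked=burned)
        burned[fire.rows, fire.cols] = True
        fires.append(fire)
    new_state = apply_transitions(state, burned, fires, succ_params, rng)
    new_state.year = state.year + 1
    return new_state, fires, burned


def spin_up(
    initial: LandscapeState,
    climate_sampler,
    params: FlammabilityParams,
    succ_params: SuccessionParams,
    years: int,
    rng: np.random.Generator,
) -> LandscapeState:
    """Drive the landscape to a quasi-stationary age/vegetation structure.

    Iterates annual steps under a stationary baseline climate sampler
    (``sampler(shape, rng) -> (tas, pr)``).  The returned state's year
    counter is reset to 0 so a projection can start from it.
    """
    if years < 0:
        raise ValueError("spin-up length must be >= 0")
    state = initial
    for _ in range(years):
        climate = climate_sampler(state.shape, rng)
        state, _, _ = step_year(state, climate, params, succ_params, rng)
    state = state.copy()
    state.year = 0
    return state


def run_ensemble(
    initial: LandscapeState,
    climate: ClimateCube,
    params: FlammabilityParams,
    succ_params: SuccessionParams,
    n_runs: int,
    seed: int,
    spinup_years: int = 0,
    spinup_sampler=None,
) -> RunEnsemble:
    """Replicate ensemble of annual simulations under one climate scenario.

    Each replicate runs from an independent child RNG stream and, when
    ``spinup_years > 0``, from its own independently spun-up copy of the
    initial landscape.  Start-of-year vegetation/age snapshots are stored
    for every run-year so habitat series can be computed annually.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n_years = climate.n_years
    n_rows, n_cols = initial.shape
    burn = np.zeros((n_runs, n_years, n_rows, n_cols), dtype=bool)
    veg = np.zeros((n_runs, n_years, n_rows, n_cols), dtype=np.int8)
    age = np.zeros((n_runs, n_years, n_rows, n_cols), dtype=np.int32)
    fires: list[list[list[FireEvent]]] = []
    if spinup_sampler is None:
        spinup_sampler = BaselineClimateSampler()
    children = np.random.SeedSequence(seed).spawn(n_runs)
    for run, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = initial.copy()
        if spinup_years > 0:
            state = spin_up(state, spinup_sampler, params, succ_params,
                            spinup_years, rng)
        run_fires: list[list[FireEvent]] = []
        for y in range(1, n_years + 1):
            veg[run, y - 1] = state.veg
            age[run, y - 1] = state.age
            state, year_fires, burned = step_year(
                state, climate.year(y), params, succ_params, rng
            )
            burn[run, y - 1] = burned
            run_fires.append(year_fires)
        fires.append(run_fires)
    return RunEnsemble(
        burn=burn, veg=veg, age=age, fires=fires,
        pixel_area=initial.pixel_area, label=climate.label,
    )
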