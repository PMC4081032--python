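"""Reusable desk-scale experiment harnesses.

These compose the generators, the simulator and the habitat analytics into
the paired-scenario design used to study the warm-versus-hot contrast: the
two trajectories run on the identical landscape from the identical seed, so
every difference in outcome is attributable to the climate trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fire_sim import FlammabilityParams, run_ensemble
from .habitat_analysis import HabitatConfig, classify_winter_habitat
from .succession import SuccessionParams
from .synthetic_data import (
    DomainConfig,
    default_scenario_pair,
    generate_climate,
    generate_range_masks,
)
from .synthetic_data import generate_landscape
from .types import LandscapeState, RangeMask, VegClass

__all__ = [
    "make_contrasting_landscape",
    "PairedScenarioOutcome",
    "paired_scenario_outcome",
]

# tundra-dominated composition (arctic/montane end of the domain)
_TUNDRA_PROPS = {
    VegClass.ROCK_ICE: 0.05,
    VegClass.TUNDRA: 0.75,
    VegClass.BLACK_SPRUCE: 0.08,
    VegClass.WHITE_SPRUCE: 0.04,
    VegClass.DECIDUOUS: 0.08,
}
# boreal-forest-dominated composition
_BOREAL_PROPS = {
    VegClass.ROCK_ICE: 0.05,
    VegClass.TUNDRA: 0.10,
    VegClass.BLACK_SPRUCE: 0.45,
    VegClass.WHITE_SPRUCE: 0.20,
    VegClass.DECIDUOUS: 0.20,
}


def make_contrasting_landscape(
    n_rows: int, n_cols: int, seed: int, pixel_area: float = 1.0
) -> tuple[LandscapeState, list[RangeMask]]:
    """A landscape with a tundra-dominated north half and a boreal south
    half, plus one range mask centred in each half.

    Emulates the structure of a domain spanning the treeline: one herd
    range sits mostly in tundra, the other mostly in spruce forest.
    """
    half = n_rows // 2
    north = generate_landscape(DomainConfig(
        n_rows=half, n_cols=n_cols, pixel_area=pixel_area,
        veg_proportions=dict(_TUNDRA_PROPS), seed=seed,
    ))
    south = generate_landscape(DomainConfig(
        n_rows=n_rows - half, n_cols=n_cols, pixel_area=pixel_area,
        veg_proportions=dict(_BOREAL_PROPS), seed=seed + 1,
    ))
    state = LandscapeState(
        veg=np.vstack([north.veg, south.veg]),
        age=np.vstack([north.age, south.age]),
        year=0, pixel_area=pixel_area,
    )
    config = DomainConfig(n_rows=n_rows, n_cols=n_cols, pixel_area=pixel_area,
                          seed=seed)
    masks = generate_range_masks(
        config,
        [("tundra_north", 0.20, (n_rows // 4, n_cols // 2)),
         ("boreal_south", 0.20, (3 * n_rows // 4, n_cols // 2))],
        seed=seed + 2,
    )
    return state, masks


@dataclass
class PairedScenarioOutcome:
    """End-of-horizon outcomes of one warm/hot pair on a shared landscape."""

    area_burned_warm: float
    area_burned_hot: float
    habitat_change_warm: float  # whole-domain percent change
    habitat_change_hot: float
    range_change_hot: dict[str, float]  # per-range percent change, hot run


def _habitat_change(ensemble, config: HabitatConfig,
                    mask: np.ndarray | None = None) -> float:
    start = classify_winter_habitat(
        (ensemble.veg[0, 0], ensemble.age[0, 0]), config)
    end = classify_winter_habitat(
        (ensemble.veg[0, -1], ensemble.age[0, -1]), config)
    if mask is not None:
        start, end = start & mask, end & mask
    s = int(start.sum())
    return 100.0 * (int(end.sum()) - s) / s


def paired_scenario_outcome(
    pair_seed: int,
    n_rows: int = 40,
    n_cols: int = 40,
    n_years: int = 90,
    spinup_years: int = 250,
    fire_params: FlammabilityParams | None = None,
    succ_params: SuccessionParams | None = None,
    habitat_config: HabitatConfig | None = None,
) -> PairedScenarioOutcome:
    """Run one paired warm/hot experiment and summarise its outcomes.

    Both scenarios start from the same landscape and the same master seed
    (hence the same spun-up initial state); only the climate cube differs.
    Single-replicate ensembles keep the per-pair cost small — the paired
    design is meant to be repeated across many seeds and judged as a
    Monte-Carlo majority, not per seed.
    """
    fire_params = fire_params or FlammabilityParams()
    succ_params = succ_params or SuccessionParams()
    habitat_config = habitat_config or HabitatConfig()
    state, masks = make_contrasting_landscape(n_rows, n_cols, seed=pair_seed)
    warm, hot = default_scenario_pair(seed=pair_seed + 10_000)
    ensembles = {}
    for params in (warm, hot):
        cube = generate_climate(params, n_years, state.shape)
        ensembles[params.label] = run_ensemble(
            state, cube, fire_params, succ_params, n_runs=1,
            seed=pair_seed + 20_000, spinup_years=spinup_years,
        )
    return PairedScenarioOutcome(
        area_burned_warm=float(ensembles["warm"].area_burned_matrix().sum()),
        area_burned_hot=float(ensembles["hot"].area_burned_matrix().sum()),
        habitat_change_warm=_habitat_change(ensembles["warm"], habitat_config),
        habitat_change_hot=_habitat_change(ensembles["hot"], habitat_config),
        range_change_hot={
            rm.name: _habitat_change(ensembles["hot"], habitat_config, rm.mask)
            for rm in masks
        },
    )
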