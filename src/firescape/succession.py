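"""Post-fire vegetation transitions, probabilistic transition times and
annual aging.

The transition graph is deliberately closed: burned spruce (black or white)
becomes early-successional deciduous; burned deciduous and burned tundra
self-replace; deciduous matures back to a climax spruce class after a
probabilistic delay; rock/ice is inert.  There is no treeline movement —
tundra never becomes forest and forest never becomes tundra.

Fire severity enters through fire area: larger fires lengthen the sampled
deciduous-to-spruce transition time via a multiplier
``1 + k * log10(size_km2 + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AGE_SENTINEL, FireEvent, LandscapeState, VegClass

__all__ = ["SuccessionParams", "sample_transition_time", "apply_transitions"]


@dataclass
class SuccessionParams:
    """Tunables of the succession pathway.

    spruce_target_prob
        Probability a burned spruce stand's scheduled climax is its own
        species (black stays black, white stays white); otherwise the
        trajectory switches to the other spruce class.
    deciduous_to_spruce_time
        (min, max) years of the uniform window for the deciduous-to-climax
        transition, before severity scaling.  The default (25, 75) brackets
        the 60-year lichen-recovery horizon so habitat dynamics are
        exercised rather than assumed.
    severity_k
        Coefficient of the fire-size severity multiplier
        ``1 + severity_k * log10(size_km2 + 1)``; 0 disables severity.
    deciduous_black_prob
        Probability an initially unscheduled deciduous stand is assigned a
        black- (vs white-) spruce climax.
    """

    spruce_target_prob: float = 0.9
    deciduous_to_spruce_time: tuple[float, float] = (25.0, 75.0)
    severity_k: float = 0.5
    deciduous_black_prob: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.deciduous_to_spruce_time
        if lo <= 0 or hi < lo:
            raise ValueError("transition-time bounds must be positive and ordered")
        if not 0.0 <= self.spruce_target_prob <= 1.0:
            raise ValueError("spruce_target_prob must be a probability")
        if self.severity_k < 0:
            raise ValueError("severity_k must be >= 0 (multiplier stays >= 1)")


def severity_multiplier(fire_size_km2: float, params: SuccessionParams) -> float:
    """Severity scaling of transition times; >= 1, increasing in fire size."""
    return 1.0 + params.severity_k * np.log10(fire_size_km2 + 1.0)


def sample_transition_time(
    fire_size_km2: float, params: SuccessionParams, rng: np.random.Generator
) -> int:
    """Sample a deciduous-to-climax-spruce transition time in years.

    Uniform on the configured window, scaled by the fire-size severity
    multiplier and rounded to the nearest integer (at least 1 year).
    """
    lo, hi = params.deciduous_to_spruce_time
    base = rng.uniform(lo, hi)
    years = int(round(base * severity_multiplier(fire_size_km2, params)))
    return max(1, years)


def _fire_size_map(shape: tuple[int, int], fires: list[FireEvent],
                   pixel_area: float) -> np.ndarray:
    """Per-pixel size (km²) of the fire that burned each pixel this year."""
    sizes = np.full(shape, pixel_area, dtype=float)
    for fire in fires:
        sizes[fire.rows, fire.cols] = fire.size_km2
    return sizes


def apply_transitions(
    state: LandscapeState,
    burn_mask: np.ndarray,
    fires: list[FireEvent],
    params: SuccessionParams,
    rng: np.random.Generator,
) -> LandscapeState:
    """Advance the landscape one year given this year's burns.

    Burned spruce becomes deciduous at age 0 with a scheduled return to a
    climax spruce class; burned deciduous and tundra self-replace at age 0
    (deciduous is rescheduled — repeated burning keeps deferring the climax
    stage); unburned fuel pixels age by one year; unburned deciduous whose
    age reaches its due age matures to its climax spruce class with age
    preserved (habitat classification is by time since fire, not time in
    class).  Returns the next year's state; the caller advances ``year``.
    """
    burn_mask = np.asarray(burn_mask, dtype=bool)
    if burn_mask.shape != state.shape:
        raise ValueError("burn mask shape does not match the landscape")
    if burn_mask[state.rock_ice].any():
        raise ValueError("burn mask includes rock/ice pixels")

    new = state.copy()
    rock = state.rock_ice
    veg = state.veg

    # aging of everything that did not burn (rock/ice keeps its sentinel)
    unburned_fuel = ~burn_mask & ~rock
    new.age[unburned_fuel] += 1

    sizes = _fire_size_map(state.shape, fires, state.pixel_area)

    # burned pixels: reset clock; spruce converts to deciduous
    burned_rows, burned_cols = np.nonzero(burn_mask)
    for r, c in zip(burned_rows, burned_cols):
        cls = VegClass(int(veg[r, c]))
        new.age[r, c] = 0
        if cls in (VegClass.BLACK_SPRUCE, VegClass.WHITE_SPRUCE):
            new.veg[r, c] = VegClass.DECIDUOUS
            if rng.random() < params.spruce_target_prob:
                target = cls
            else:
                target = (VegClass.WHITE_SPRUCE if cls is VegClass.BLACK_SPRUCE
                          else VegClass.BLACK_SPRUCE)
            new.pending_target[r, c] = target
            new.pending_due[r, c] = sample_transition_time(sizes[r, c], params, rng)
        elif cls is VegClass.DECIDUOUS:
            # self-replacement: keep (or assign) the climax target, defer it
            if new.pending_target[r, c] < 0:
                new.pending_target[r, c] = (
                    VegClass.BLACK_SPRUCE
                    if rng.random() < params.deciduous_black_prob
                    else VegClass.WHITE_SPRUCE
                )
            new.pending_due[r, c] = sample_transition_time(sizes[r, c], params, rng)
        # tundra self-replaces with no schedule

    # deciduous stands that have never been scheduled (initial landscape)
    # get a climax trajectory now, unscaled by severity
    fresh = (veg == VegClass.DECIDUOUS) & ~burn_mask & (state.pending_target < 0)
    for r, c in zip(*np.nonzero(fresh)):
        new.pending_target[r, c] = (
            VegClass.BLACK_SPRUCE if rng.random() < params.deciduous_black_prob
            else VegClass.WHITE_SPRUCE
        )
        new.pending_due[r, c] = sample_transition_time(0.0, params, rng)

    # maturation: unburned deciduous reaching its due age becomes climax
    # spruce; stand age (time since fire) is preserved
    mature = (
        (new.veg == VegClass.DECIDUOUS)
        & ~burn_mask
        & (new.pending_target >= 0)
        & (new.age >= new.pending_due)
    )
    new.veg[mature] = new.pending_target[mature]
    new.pending_target[mature] = -1
    new.pending_due[mature] = 0

    # schedules only live on deciduous pixels
    not_decid = new.veg != VegClass.DECIDUOUS
    new.pending_target[not_decid] = -1
    new.pending_due[not_decid] = 0

    assert np.all(new.age[rock] == AGE_SENTINEL)
    return new
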