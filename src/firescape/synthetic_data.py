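"""Synthetic landscapes, two-scenario climate trajectories, range masks and
historical fire records.

Real inputs for this kind of analysis are a reclassified land-cover raster,
delta-downscaled GCM climate fields, herd-range polygons and burn-perimeter
databases.  None of those are needed to exercise the model: this module
generates rasters with the same structure — a patchy five-class vegetation
map with stand ages, annual growing-season temperature/precipitation cubes
for a contrasting "warm"/"hot" scenario pair, connected range blobs, and a
multi-decade labelled fire record — all reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import (
    AGE_SENTINEL,
    ClimateCube,
    HistoricalFireRecord,
    LandscapeState,
    RangeMask,
    VegClass,
)

__all__ = [
    "DomainConfig",
    "ClimateScenarioParams",
    "default_scenario_pair",
    "generate_landscape",
    "generate_climate",
    "generate_range_masks",
    "generate_historical_record",
]

_N8 = np.ones((3, 3), dtype=bool)  # 8-neighbourhood structuring element

_DEFAULT_PROPORTIONS = {
    VegClass.ROCK_ICE: 0.05,
    VegClass.TUNDRA: 0.40,
    VegClass.BLACK_SPRUCE: 0.25,
    VegClass.WHITE_SPRUCE: 0.10,
    VegClass.DECIDUOUS: 0.20,
}


@dataclass
class DomainConfig:
    """Domain geometry, vegetation composition and initial-age parameters.

    ``pixel_area`` is km² per pixel (default 1, the model's native
    resolution).  ``mean_initial_age`` is the mean of the geometric
    time-since-fire distribution used for initial stand ages; 80 y is the
    stationary mean of a constant-hazard regime with roughly a 1%/yr burn
    probability, which the spin-up converges towards.
    """

    n_rows: int
    n_cols: int
    pixel_area: float = 1.0
    veg_proportions: dict[VegClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    mean_initial_age: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows * self.n_cols < 9:
            raise ValueError("domain must contain at least 9 pixels")
        props = {VegClass(k): float(v) for k, v in self.veg_proportions.items()}
        unknown = set(props) - set(VegClass)
        if unknown:
            raise ValueError(f"unknown vegetation classes: {unknown}")
        if any(v < 0 for v in props.values()):
            raise ValueError("vegetation proportions must be non-negative")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"vegetation proportions sum to {total}, not 1")
        # fill missing classes with zero so downstream code can index freely
        self.veg_proportions = {c: props.get(c, 0.0) for c in VegClass}
        if self.mean_initial_age <= 0:
            raise ValueError("mean initial age must be positive")


@dataclass
class ClimateScenarioParams:
    """Trend-plus-noise parameterisation of one climate trajectory.

    Temperature for 1-based simulation year ``y`` at grid row ``r`` is
    ``t0 + t_trend * y/10 + spatial_gradient * r + noise`` (°C); the
    growing-season precipitation field is analogous in mm.  The warm/hot
    contrast of a scenario pair is carried entirely by the trends.
    """

    label: str
    t0: float = 11.0
    t_trend: float = 0.3  # °C per decade
    p0: float = 300.0
    p_trend: float = 5.0  # mm per decade
    noise_sd_t: float = 0.8
    noise_sd_p: float = 30.0
    spatial_gradient: float = 0.0  # °C per row, latitudinal proxy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("warm", "hot"):
            raise ValueError("scenario label must be 'warm' or 'hot'")
        if self.noise_sd_t < 0 or self.noise_sd_p < 0:
            raise ValueError("noise standard deviations must be >= 0")


def default_scenario_pair(
    seed: int = 0,
    warm_trend: float = 0.3,
    hot_trend: float = 0.6,
    **common,
) -> tuple[ClimateScenarioParams, ClimateScenarioParams]:
    """A warm/hot scenario pair differing only in warming trend.

    Defaults (0.3 vs 0.6 °C/decade) bracket mid-range high-latitude
    projections under a moderate emissions pathway: about +2.7 °C versus
    +5.4 °C of growing-season warming over nine decades.
    """
    if hot_trend < warm_trend:
        raise ValueError("hot scenario trend must be >= warm scenario trend")
    warm = ClimateScenarioParams(label="warm", t_trend=warm_trend, seed=seed, **common)
    hot = ClimateScenarioParams(label="hot", t_trend=hot_trend, seed=seed + 1, **common)
    return warm, hot


def _majority_filter(veg: np.ndarray, passes: int = 3) -> np.ndarray:
    """Majority (mode) filter over the 8-neighbourhood, ties to lowest class."""
    out = veg.copy()
    kernel = np.ones((3, 3))
    for _ in range(passes):
        counts = np.stack(
            [ndimage.convolve((out == c).astype(np.int16), kernel, mode="nearest")
             for c in VegClass]
        )
        out = np.argmax(counts, axis=0).astype(np.int8)
    return out


def _repair_counts(veg: np.ndarray, targets: dict[VegClass, int],
                   rng: np.random.Generator) -> np.ndarray:
    """Flip pixels until class counts equal targets exactly.

    Smoothing erodes minority classes; this pass flips surplus-class pixels
    that are 8-adjacent to a deficit class over to that class (preserving
    patch structure), falling back to random pixels when a class has no
    patch left to grow from.
    """
    veg = veg.copy()
    for _ in range(200):
        counts = {c: int((veg == c).sum()) for c in VegClass}
        deficits = {c: targets[c] - counts[c] for c in VegClass if targets[c] > counts[c]}
        if not deficits:
            break
        surplus = {c: counts[c] - targets[c] for c in VegClass if counts[c] > targets[c]}
        for c, need in deficits.items():
            if need <= 0:
                continue
            if counts[c] > 0:
                frontier = ndimage.binary_dilation(veg == c, structure=_N8) & (veg != c)
            else:
                frontier = np.ones_like(veg, dtype=bool)
            cand_mask = frontier & np.isin(veg, [s for s, n in surplus.items() if n > 0])
            rows, cols = np.nonzero(cand_mask)
            if rows.size == 0:
                continue
            take = min(need, rows.size)
            idx = rng.choice(rows.size, size=take, replace=False)
            for i in idx:
                donor = VegClass(int(veg[rows[i], cols[i]]))
                if surplus.get(donor, 0) <= 0:
                    continue
                veg[rows[i], cols[i]] = c
                surplus[donor] -= 1
    return veg


def _target_counts(proportions: dict[VegClass, float], n: int) -> dict[VegClass, int]:
    """Integer class counts summing to n (largest-remainder apportionment)."""
    raw = {c: proportions[c] * n for c in VegClass}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(VegClass, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_landscape(config: DomainConfig) -> LandscapeState:
    """Generate a patchy five-class vegetation grid with initial stand ages.

    Pixels are drawn from a per-pixel multinomial on the configured
    proportions, smoothed into patches by three majority-filter passes,
    then nudged back to the exact target composition.  Stand ages are
    geometric with mean ``config.mean_initial_age``; rock/ice pixels carry
    the age sentinel −1.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    n = config.n_rows * config.n_cols
    props = np.array([config.veg_proportions[c] for c in VegClass])
    veg = rng.choice(len(VegClass), size=shape, p=props).astype(np.int8)
    if np.count_nonzero(props > 0) > 1:
        veg = _majority_filter(veg, passes=3)
        veg = _repair_counts(veg, _target_counts(config.veg_proportions, n), rng)
    # geometric on {0,1,2,...} with mean m has success prob 1/(m+1)
    p_geo = 1.0 / (config.mean_initial_age + 1.0)
    age = (rng.geometric(p_geo, size=shape) - 1).astype(np.int32)
    age[veg == VegClass.ROCK_ICE] = AGE_SENTINEL
    return LandscapeState(veg=veg, age=age, year=0, pixel_area=config.pixel_area)


def generate_climate(params: ClimateScenarioParams, n_years: int,
                     shape: tuple[int, int]) -> ClimateCube:
    """Annual growing-season temperature/precipitation cube for one scenario.

    Noise is white in time and space.  Precipitation is floored at zero.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(params.seed)
    n_rows, n_cols = shape
    years = np.arange(1, n_years + 1, dtype=float)[:, None, None]
    rows = np.arange(n_rows, dtype=float)[None, :, None]
    tas = (
        params.t0
        + params.t_trend * years / 10.0
        + params.spatial_gradient * rows
        + np.zeros((1, 1, n_cols))
    )
    pr = params.p0 + params.p_trend * years / 10.0 + np.zeros((1, n_rows, n_cols))
    tas = np.broadcast_to(tas, (n_years, n_rows, n_cols)).copy()
    pr = np.broadcast_to(pr, (n_years, n_rows, n_cols)).copy()
    if params.noise_sd_t > 0:
        tas += rng.normal(0.0, params.noise_sd_t, size=tas.shape)
    if params.noise_sd_p > 0:
        pr += rng.normal(0.0, params.noise_sd_p, size=pr.shape)
    np.maximum(pr, 0.0, out=pr)
    return ClimateCube(tas=tas, pr=pr, label=params.label)


def generate_range_masks(
    config: DomainConfig,
    specs: list[tuple[str, float, tuple[int, int]]],
    seed: int | None = None,
) -> list[RangeMask]:
    """Connected range blobs grown around anchors to target area fractions.

    Masks are built in list order by repeated 8-neighbour dilation from the
    anchor; the final dilation ring is subsampled at random to land on the
    target pixel count exactly.  Independently grown masks may overlap.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = (config.n_rows, config.n_cols)
    n = config.n_rows * config.n_cols
    masks: list[RangeMask] = []
    for name, fraction, anchor in specs:
        if not 0.0 < fraction <= 1.0:
            raise ValueError(f"target fraction for {name!r} must be in (0, 1]")
        r, c = anchor
        if not (0 <= r < config.n_rows and 0 <= c < config.n_cols):
            raise ValueError(f"anchor for {name!r} outside the grid")
        target = max(1, int(round(fraction * n)))
        mask = np.zeros(shape, dtype=bool)
        mask[r, c] = True
        while mask.sum() < target:
            ring = ndimage.binary_dilation(mask, structure=_N8) & ~mask
            ring_n = int(ring.sum())
            if ring_n == 0:  # grid exhausted
                break
            remaining = target - int(mask.sum())
            if ring_n <= remaining:
                mask |= ring
            else:
                rows, cols = np.nonzero(ring)
                idx = rng.choice(ring_n, size=remaining, replace=False)
                mask[rows[idx], cols[idx]] = True
        masks.append(RangeMask(name=name, mask=mask))
    return masks


def _grow_fire(anchor: tuple[int, int], size: int, eligible: np.ndarray,
               rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random-order region growth from anchor up to ``size`` eligible cells."""
    n_rows, n_cols = eligible.shape
    cells = [anchor]
    in_fire = {anchor}
    frontier = [anchor]
    while len(cells) < size and frontier:
        i = int(rng.integers(len(frontier)))
        r, c = frontier[i]
        neighbors = [
            (rr, cc)
            for rr in range(max(0, r - 1), min(n_rows, r + 2))
            for cc in range(max(0, c - 1), min(n_cols, c + 2))
            if (rr, cc) not in in_fire and eligible[rr, cc]
        ]
        if not neighbors:
            frontier.pop(i)
            continue
        pick = neighbors[int(rng.integers(len(neighbors)))]
        cells.append(pick)
        in_fire.add(pick)
        frontier.append(pick)
    return cells


def generate_historical_record(
    landscape: LandscapeState,
    years: int,
    burn_rate: float,
    seed: int = 0,
    mean_fire_size: float = 8.0,
    start_year: int = 1950,
    forced_fires: list[tuple[int, tuple[int, int], int]] | None = None,
) -> HistoricalFireRecord:
    """Emulated burn-perimeter record over ``years`` annual time steps.

    Each fuel pixel independently seeds a fire with probability
    ``burn_rate / mean_fire_size``; each fire grows as a random 8-connected
    region to a geometric target size with the given mean, so the expected
    annual burned fraction is ``burn_rate``.  ``forced_fires`` entries
    ``(year_label, anchor, size)`` deterministically plant a fire of an
    exact size, for constructing known-answer fixtures.
    """
    if not 0.0 <= burn_rate <= 1.0:
        raise ValueError("burn_rate must be a probability")
    if years < 1:
        raise ValueError("record must span at least one year")
    rng = np.random.default_rng(seed)
    shape = landscape.shape
    fuel = ~landscape.rock_ice
    year_labels = list(range(start_year, start_year + years))
    burn = np.zeros((years, *shape), dtype=bool)
    labels = np.zeros((years, *shape), dtype=np.int32)
    forced_by_year: dict[int, list[tuple[tuple[int, int], int]]] = {}
    for yl, anchor, size in forced_fires or []:
        forced_by_year.setdefault(yl, []).append((anchor, size))
    p_ignite = burn_rate / mean_fire_size
    for yi, yl in enumerate(year_labels):
        fire_id = 0
        burned_this_year = np.zeros(shape, dtype=bool)
        for anchor, size in forced_by_year.get(yl, []):
            eligible = fuel & ~burned_this_year
            cells = _grow_fire(anchor, size, eligible, rng)
            fire_id += 1
            for r, c in cells:
                burned_this_year[r, c] = True
                labels[yi, r, c] = fire_id
        if p_ignite > 0:
            draws = rng.random(shape)
            ig_rows, ig_cols = np.nonzero((draws < p_ignite) & fuel)
            order = rng.permutation(ig_rows.size)
            for k in order:
                anchor = (int(ig_rows[k]), int(ig_cols[k]))
                if burned_this_year[anchor]:
                    continue
                target = int(rng.geometric(1.0 / mean_fire_size))
                eligible = fuel & ~burned_this_year
                cells = _grow_fire(anchor, target, eligible, rng)
                fire_id += 1
                for r, c in cells:
                    burned_this_year[r, c] = True
                    labels[yi, r, c] = fire_id
        burn[yi] = burned_this_year
    return HistoricalFireRecord(
        years=year_labels, burn_masks=burn, fire_labels=labels,
        pixel_area=landscape.pixel_area,
    )
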