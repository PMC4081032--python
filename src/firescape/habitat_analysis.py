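"""Winter-habitat analytics over simulation ensembles.

Winter habitat for caribou is defined as lichen-producing vegetation:
tundra or spruce stands older than a time-since-fire threshold (default
strictly > 60 years — forage lichen recovery after fire takes decades).
This module classifies habitat, builds per-range habitat time series with
across-run percentile envelopes, selects the representative replicate
(highest Pearson correlation with the per-year median area-burned series),
computes relative-flammability maps and their top-quantile masks, overlaps
them with herd ranges, differences scenarios, and summarises percent
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    HABITAT_CLASSES,
    LandscapeState,
    RangeMask,
    RunEnsemble,
    SPRUCE_CLASSES,
    VegClass,
    year_to_label,
)

__all__ = [
    "HabitatConfig",
    "HabitatSummary",
    "RepresentativeRunResult",
    "FlammabilityMap",
    "classify_winter_habitat",
    "habitat_timeseries",
    "representative_run",
    "relative_flammability",
    "top_flammability_mask",
    "range_overlap_percent",
    "flammability_difference",
    "percent_change",
    "format_percent_change",
    "composition_percent",
    "nearest_rank_quantile",
    "burned_area_ratio",
]


@dataclass
class HabitatConfig:
    """Winter-habitat definition: eligible classes and age threshold.

    The threshold is a strict inequality (a stand aged exactly 60 does not
    qualify under the default); it is configurable because the boundary
    case is a modelling convention.
    """

    age_threshold: int = 60
    habitat_classes: tuple[VegClass, ...] = HABITAT_CLASSES

    def __post_init__(self) -> None:
        if self.age_threshold <= 0:
            raise ValueError("age threshold must be positive")


@dataclass
class RepresentativeRunResult:
    """Replicate most correlated with the per-year median area burned."""

    run: int
    r: float
    r_all: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class FlammabilityMap:
    """Per-pixel proportion of run-years burned, with provenance."""

    values: np.ndarray
    n_runs: int
    n_years: int
    fuel_mask: np.ndarray | None = None
    label: str = ""


@dataclass
class HabitatSummary:
    """Annual habitat areas per run and range, with percentile envelopes.

    ``per_run_year`` columns: run, year (calendar label), range,
    tundra_km2, spruce_km2, total_km2.  ``envelopes`` columns: year,
    range, p5, median, p95 of total habitat area across runs
    (nearest-rank quantiles).
    """

    per_run_year: pd.DataFrame
    envelopes: pd.DataFrame
    range_area_km2: dict[str, float]


def classify_winter_habitat(
    state: LandscapeState | tuple[np.ndarray, np.ndarray],
    config: HabitatConfig | None = None,
) -> np.ndarray:
    """Boolean mask of lichen-producing winter habitat.

    True iff the pixel's class is in ``habitat_classes`` and its
    time-since-fire strictly exceeds the age threshold.  Rock/ice (age
    sentinel −1) and deciduous never qualify.
    """
    config = config or HabitatConfig()
    if isinstance(state, LandscapeState):
        veg, age = state.veg, state.age
    else:
        veg, age = state
    eligible = np.isin(veg, [int(c) for c in config.habitat_classes])
    return eligible & (age > config.age_threshold)


def nearest_rank_quantile(values: np.ndarray, p: float) -> float:
    """Nearest-rank quantile: the ceil(p*n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("quantile of empty sample")
    rank = max(1, int(np.ceil(p * v.size)))
    return float(v[rank - 1])


def habitat_timeseries(
    ensemble: RunEnsemble,
    masks: list[RangeMask],
    config: HabitatConfig | None = None,
) -> HabitatSummary:
    """Annual habitat area (split tundra vs spruce) per run and range,
    with across-run 5th/95th nearest-rank percentile envelopes."""
    config = config or HabitatConfig()
    px = ensemble.pixel_area
    spruce_codes = [int(c) for c in SPRUCE_CLASSES]
    rows = []
    for run in range(ensemble.n_runs):
        for yi in range(ensemble.n_years):
            veg = ensemble.veg[run, yi]
            age = ensemble.age[run, yi]
            habitat = classify_winter_habitat((veg, age), config)
            is_spruce = np.isin(veg, spruce_codes)
            for rm in masks:
                h = habitat & rm.mask
                spruce_km2 = float((h & is_spruce).sum()) * px
                tundra_km2 = float((h & (veg == VegClass.TUNDRA)).sum()) * px
                rows.append(
                    {"run": run, "year": year_to_label(yi + 1), "range": rm.name,
                     "tundra_km2": tundra_km2, "spruce_km2": spruce_km2,
                     "total_km2": tundra_km2 + spruce_km2}
                )
    per_run_year = pd.DataFrame(rows)
    env_rows = []
    for (year, name), grp in per_run_year.groupby(["year", "range"]):
        totals = grp["total_km2"].to_numpy()
        env_rows.append(
            {"year": year, "range": name,
             "p5": nearest_rank_quantile(totals, 0.05),
             "median": nearest_rank_quantile(totals, 0.5),
             "p95": nearest_rank_quantile(totals, 0.95)}
        )
    return HabitatSummary(
        per_run_year=per_run_year,
        envelopes=pd.DataFrame(env_rows),
        range_area_km2={rm.name: rm.n_pixels * px for rm in masks},
    )


def representative_run(
    data: RunEnsemble | np.ndarray,
) -> RepresentativeRunResult:
    """Select the replicate whose annual area-burned series correlates most
    (Pearson r) with the per-year across-run median series.

    Replicates with a constant series have undefined correlation and are
    excluded; ties at the maximum r break to the lowest run index.
    """
    matrix = data.area_burned_matrix() if isinstance(data, RunEnsemble) else (
        np.asarray(data, dtype=float)
    )
    n_runs, n_years = matrix.shape
    if n_runs < 2 or n_years < 3:
        raise ValueError("need >= 2 runs and >= 3 years")
    median = np.median(matrix, axis=0)
    if np.ptp(median) == 0:
        raise ValueError("per-year median series is constant; r undefined")
    r_all = np.full(n_runs, np.nan)
    for i in range(n_runs):
        if np.ptp(matrix[i]) == 0:
            continue
        r_all[i] = np.corrcoef(matrix[i], median)[0, 1]
    if np.all(np.isnan(r_all)):
        raise ValueError("all run series are constant; r undefined")
    best = int(np.nanargmax(r_all))
    return RepresentativeRunResult(run=best, r=float(r_all[best]), r_all=r_all)


def relative_flammability(ensemble: RunEnsemble) -> FlammabilityMap:
    """Proportion of all run-years in which each pixel burned."""
    counts = ensemble.burn.sum(axis=(0, 1)).astype(float)
    values = counts / (ensemble.n_runs * ensemble.n_years)
    fuel = ensemble.veg[0, 0] != VegClass.ROCK_ICE
    return FlammabilityMap(
        values=values, n_runs=ensemble.n_runs, n_years=ensemble.n_years,
        fuel_mask=fuel, label=ensemble.label,
    )


def top_flammability_mask(fmap: FlammabilityMap, fraction: float = 0.2) -> np.ndarray:
    """Pixels in the top ``fraction`` of relative flammability.

    The threshold is the k-th largest value among fuel (non-rock/ice)
    pixels with k = round(fraction * n_fuel); ties at the threshold are all
    included, so the mask can exceed the nominal fraction (on an all-equal
    map it covers the whole fuel domain).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    fuel = fmap.fuel_mask if fmap.fuel_mask is not None else np.ones(
        fmap.values.shape, dtype=bool
    )
    vals = fmap.values[fuel]
    k = max(1, int(round(fraction * vals.size)))
    threshold = np.sort(vals)[-k]
    return fuel & (fmap.values >= threshold)


def range_overlap_percent(mask: np.ndarray, range_mask: RangeMask) -> float:
    """Percent of a herd's range covered by the given mask."""
    if mask.shape != range_mask.mask.shape:
        raise ValueError("mask shapes differ")
    denom = range_mask.n_pixels
    return 100.0 * float((mask & range_mask.mask).sum()) / denom


def flammability_difference(map_a: FlammabilityMap,
                            map_b: FlammabilityMap) -> np.ndarray:
    """Per-pixel difference ``map_b − map_a``.

    With ``map_a`` the warm and ``map_b`` the hot scenario this is the
    hot − warm convention: positive values mark pixels that burn more
    often under the hotter trajectory.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("flammability maps have different shapes")
    if (map_a.n_runs, map_a.n_years) != (map_b.n_runs, map_b.n_years):
        raise ValueError("flammability maps have different provenance")
    return map_b.values - map_a.values


def percent_change(area_start: float, area_end: float) -> float:
    """Signed percent change 100·(end − start)/start."""
    if area_start <= 0:
        raise ValueError("starting area must be positive")
    return 100.0 * (area_end - area_start) / area_start


def format_percent_change(value: float) -> float:
    """Round for reporting: integer percent when |x| >= 1, else 1 decimal."""
    if abs(value) >= 1.0:
        return float(round(value))
    return float(round(value, 1))


def composition_percent(
    summary: HabitatSummary | tuple[float, float],
    year: int | None = None,
    range_name: str | None = None,
    run: int | None = None,
) -> tuple[float, float]:
    """Habitat composition (tundra %, spruce %) of total habitat area.

    Accepts either a ``(tundra_km2, spruce_km2)`` pair or a HabitatSummary
    plus a year / range (and optionally a run; otherwise areas are averaged
    across runs first).
    """
    if isinstance(summary, HabitatSummary):
        df = summary.per_run_year
        sel = (df["year"] == year) & (df["range"] == range_name)
        if run is not None:
            sel &= df["run"] == run
        grp = df[sel]
        if grp.empty:
            raise ValueError("no habitat rows match the selection")
        tundra = float(grp["tundra_km2"].mean())
        spruce = float(grp["spruce_km2"].mean())
    else:
        tundra, spruce = summary
    total = tundra + spruce
    if total <= 0:
        raise ValueError("composition of zero habitat is undefined")
    return 100.0 * tundra / total, 100.0 * spruce / total


def burned_area_ratio(stats_hot, stats_warm) -> float:
    """Ratio of mean annual area burned, hot over warm regime."""
    denom = stats_warm.annual_area_mean()
    if denom == 0:
        raise ValueError("warm regime burned no area; ratio undefined")
    return stats_hot.annual_area_mean() / denom
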