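"""Fire-regime statistics (number of fires, mean fire size, annual area
burned) from labelled burn records or simulated ensembles, plus the
comparison-based calibration between simulated and reference regimes.

A fire counts toward a spatial mask or vegetation-class filter if at least
one of its burned pixels intersects the filter; its contribution to area
sums is the intersected area, which keeps areas additive across disjoint
class filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    HistoricalFireRecord,
    RangeMask,
    RunEnsemble,
    VegClass,
    year_to_label,
)

__all__ = [
    "FireRegimeStats",
    "fires_from_record",
    "fires_from_ensemble_run",
    "regime_stats",
    "calibration_distance",
    "grid_search_calibration",
    "sim_decade_of",
]

# one fire = (rows, cols) pixel index arrays
Fire = tuple[np.ndarray, np.ndarray]


def sim_decade_of(year_label: int) -> str:
    """Decade label for simulation calendar years (2011-2020 -> "2010s")."""
    return f"{((year_label - 1) // 10) * 10}s"


def calendar_decade_of(year_label: int) -> str:
    """Conventional decade label (1950-1959 -> "1950s")."""
    return f"{(year_label // 10) * 10}s"


@dataclass
class FireRegimeStats:
    """Per-year fire characteristics and their decadal summaries.

    ``per_year`` has columns ``year``, ``n_fires``, ``mean_size_km2``,
    ``total_area_km2`` (total = n_fires * mean_size up to rounding).
    """

    per_year: pd.DataFrame
    decade_of: Callable[[int], str] = calendar_decade_of

    @property
    def years(self) -> np.ndarray:
        return self.per_year["year"].to_numpy()

    @property
    def n_years(self) -> int:
        return len(self.per_year)

    def annual_count_mean(self) -> float:
        return float(self.per_year["n_fires"].mean())

    def overall_mean_size(self) -> float:
        """Area-per-fire over the whole period (0 when there were no fires)."""
        n = self.per_year["n_fires"].sum()
        if n == 0:
            return 0.0
        return float(self.per_year["total_area_km2"].sum() / n)

    def annual_area_mean(self) -> float:
        return float(self.per_year["total_area_km2"].mean())

    def decadal(self) -> pd.DataFrame:
        """Decadal mean and sample SD (ddof=1) of the three annual series."""
        df = self.per_year.copy()
        df["decade"] = [self.decade_of(int(y)) for y in df["year"]]
        agg = df.groupby("decade").agg(
            n_fires_mean=("n_fires", "mean"),
            n_fires_sd=("n_fires", lambda s: s.std(ddof=1)),
            size_mean=("mean_size_km2", "mean"),
            size_sd=("mean_size_km2", lambda s: s.std(ddof=1)),
            area_mean=("total_area_km2", "mean"),
            area_sd=("total_area_km2", lambda s: s.std(ddof=1)),
        )
        return agg.reset_index()


def fires_from_record(record: HistoricalFireRecord) -> dict[int, list[Fire]]:
    """Per-year fire pixel sets from a labelled burn record."""
    out: dict[int, list[Fire]] = {}
    for yi, year in enumerate(record.years):
        labels = record.fire_labels[yi]
        fires: list[Fire] = []
        for fid in np.unique(labels[labels > 0]):
            rows, cols = np.nonzero(labels == fid)
            fires.append((rows, cols))
        out[year] = fires
    return out


def fires_from_ensemble_run(ensemble: RunEnsemble, run: int) -> dict[int, list[Fire]]:
    """Per-year fire pixel sets for one ensemble replicate (calendar labels)."""
    out: dict[int, list[Fire]] = {}
    for yi in range(ensemble.n_years):
        out[year_to_label(yi + 1)] = [
            (f.rows, f.cols) for f in ensemble.fires[run][yi]
        ]
    return out


def _filter_mask(
    shape: tuple[int, int],
    mask: RangeMask | np.ndarray | None,
    class_filter: Iterable[VegClass] | None,
    veg: np.ndarray | None,
) -> np.ndarray:
    keep = np.ones(shape, dtype=bool)
    if mask is not None:
        m = mask.mask if isinstance(mask, RangeMask) else np.asarray(mask, bool)
        if not m.any():
            raise ValueError("empty region mask")
        keep &= m
    if class_filter is not None:
        if veg is None:
            raise ValueError("class filter requires a vegetation grid")
        keep &= np.isin(veg, [int(c) for c in class_filter])
    return keep


def regime_stats(
    fires_by_year: dict[int, list[Fire]],
    pixel_area: float = 1.0,
    mask: RangeMask | np.ndarray | None = None,
    class_filter: Iterable[VegClass] | None = None,
    veg_by_year: Callable[[int], np.ndarray] | np.ndarray | None = None,
    grid_shape: tuple[int, int] | None = None,
    decade_of: Callable[[int], str] = calendar_decade_of,
) -> FireRegimeStats:
    """Annual fire-regime statistics under optional spatial/class filters.

    A fire is counted if >= 1 burned pixel intersects the filter, and its
    area is the intersected area.  ``veg_by_year`` supplies the vegetation
    grid fires burned on (a static grid, or a callable of the year label)
    when a class filter is used.
    """
    if grid_shape is None:
        if isinstance(mask, RangeMask):
            grid_shape = mask.mask.shape
        elif mask is not None:
            grid_shape = np.asarray(mask).shape
        elif isinstance(veg_by_year, np.ndarray):
            grid_shape = veg_by_year.shape
        else:
            for fires in fires_by_year.values():
                for rows, cols in fires:
                    if rows.size:
                        grid_shape = (int(rows.max()) + 1, int(cols.max()) + 1)
            if grid_shape is None:
                grid_shape = (1, 1)
    records = []
    for year in sorted(fires_by_year):
        if callable(veg_by_year):
            veg = veg_by_year(year)
        else:
            veg = veg_by_year
        keep = _filter_mask(grid_shape, mask, class_filter, veg)
        sizes = []
        for rows, cols in fires_by_year[year]:
            inter = int(keep[rows, cols].sum())
            if inter > 0:
                sizes.append(inter * pixel_area)
        n = len(sizes)
        total = float(sum(sizes))
        records.append(
            {"year": year, "n_fires": n,
             "mean_size_km2": total / n if n else 0.0,
             "total_area_km2": total}
        )
    return FireRegimeStats(per_year=pd.DataFrame(records), decade_of=decade_of)


def calibration_distance(simulated: FireRegimeStats,
                         historical: FireRegimeStats) -> float:
    """Normalised squared distance between two fire regimes.

    Sums squared relative errors over (mean annual fire count, overall mean
    fire size, mean annual area burned), each scaled by the historical
    value; a zero historical value degrades that term to a squared absolute
    difference.  Zero iff all three summaries match.
    """
    if simulated.n_years != historical.n_years:
        raise ValueError("regimes must cover matching period lengths")
    total = 0.0
    for s, h in (
        (simulated.annual_count_mean(), historical.annual_count_mean()),
        (simulated.overall_mean_size(), historical.overall_mean_size()),
        (simulated.annual_area_mean(), historical.annual_area_mean()),
    ):
        total += ((s - h) / h) ** 2 if h != 0 else (s - h) ** 2
    return total


def grid_search_calibration(
    candidates: Sequence[float],
    simulate_fn: Callable[[float], FireRegimeStats],
    historical: FireRegimeStats,
) -> tuple[float, np.ndarray]:
    """Comparison-based calibration: evaluate the regime distance on a
    parameter grid and return (best parameter value, distances).

    This mirrors how landscape fire models are calibrated in practice —
    simulate under each candidate, compare summary statistics against the
    reference regime, keep the closest — rather than gradient fitting.
    """
    distances = np.array(
        [calibration_distance(simulate_fn(v), historical) for v in candidates]
    )
    best = int(np.argmin(distances))
    return float(candidates[best]), distances
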