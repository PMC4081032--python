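"""Core data containers shared across the simulation and analysis modules.

The lattice convention throughout the package:

* vegetation is an integer-coded grid over five classes (rock/ice, tundra,
  black spruce, white spruce, deciduous);
* stand age is years since the pixel last burned, with ``-1`` as the
  sentinel for rock/ice, which carries no fuel and never burns;
* simulation years are indexed ``1..n_years`` and mapped onto calendar
  labels ``2011..`` so that decade ``d`` covers years ``10(d-1)+1 .. 10d``
  and is labelled ``"2010s"``, ``"2020s"`` and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "VegClass",
    "AGE_SENTINEL",
    "FUEL_CLASSES",
    "SPRUCE_CLASSES",
    "HABITAT_CLASSES",
    "LandscapeState",
    "FireEvent",
    "ClimateCube",
    "RangeMask",
    "HistoricalFireRecord",
    "RunEnsemble",
    "year_to_label",
    "decade_label",
]


class VegClass(IntEnum):
    """Vegetation classes of the frame-based succession model."""

    ROCK_ICE = 0
    TUNDRA = 1
    BLACK_SPRUCE = 2
    WHITE_SPRUCE = 3
    DECIDUOUS = 4


#: age value carried by rock/ice pixels (no fuel, never burns)
AGE_SENTINEL = -1

#: classes that carry fuel and can burn
FUEL_CLASSES = (
    VegClass.TUNDRA,
    VegClass.BLACK_SPRUCE,
    VegClass.WHITE_SPRUCE,
    VegClass.DECIDUOUS,
)

SPRUCE_CLASSES = (VegClass.BLACK_SPRUCE, VegClass.WHITE_SPRUCE)

#: lichen-producing classes used by the winter-habitat definition
HABITAT_CLASSES = (VegClass.TUNDRA, VegClass.BLACK_SPRUCE, VegClass.WHITE_SPRUCE)

#: calendar year corresponding to simulation year 1
CALENDAR_ORIGIN = 2010


def year_to_label(year_index: int) -> int:
    """Map simulation year (1-based) to a calendar-year label (2011..)."""
    return CALENDAR_ORIGIN + int(year_index)


def decade_label(year_index: int) -> str:
    """Decade label for a 1-based simulation year (years 1-10 -> "2010s")."""
    if year_index < 1:
        raise ValueError("simulation years are 1-based")
    return f"{CALENDAR_ORIGIN + 10 * ((int(year_index) - 1) // 10)}s"


@dataclass
class LandscapeState:
    """Per-pixel vegetation class and stand age on a rectangular lattice.

    ``pending_target`` / ``pending_due`` hold the succession schedule:
    for a deciduous pixel they give the climax spruce class it will
    transition to and the stand age at which that happens.  ``-1`` /
    ``0`` mean "no pending transition".
    """

    veg: np.ndarray
    age: np.ndarray
    year: int = 0
    pixel_area: float = 1.0
    pending_target: np.ndarray = field(default=None)  # type: ignore[assignment]
    pending_due: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.veg = np.asarray(self.veg, dtype=np.int8)
        self.age = np.asarray(self.age, dtype=np.int32)
        if self.veg.shape != self.age.shape:
            raise ValueError("veg and age grids must share shape")
        if self.pending_target is None:
            self.pending_target = np.full(self.veg.shape, -1, dtype=np.int8)
        if self.pending_due is None:
            self.pending_due = np.zeros(self.veg.shape, dtype=np.int32)
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.veg.shape

    @property
    def rock_ice(self) -> np.ndarray:
        return self.veg == VegClass.ROCK_ICE

    def validate(self) -> None:
        rock = self.veg == VegClass.ROCK_ICE
        if not np.all(self.age[rock] == AGE_SENTINEL):
            raise ValueError("rock/ice pixels must carry the age sentinel -1")
        if not np.all(self.age[~rock] >= 0):
            raise ValueError("fuel-class pixels must have age >= 0")
        if self.veg.min() < 0 or self.veg.max() > max(VegClass):
            raise ValueError("vegetation codes outside the declared classes")

    def copy(self) -> "LandscapeState":
        return LandscapeState(
            veg=self.veg.copy(),
            age=self.age.copy(),
            year=self.year,
            pixel_area=self.pixel_area,
            pending_target=self.pending_target.copy(),
            pending_due=self.pending_due.copy(),
        )


@dataclass
class FireEvent:
    """One fire: ignition cell, burned cell set, year, and size in km²."""

    year: int
    ignition: tuple[int, int]
    rows: np.ndarray
    cols: np.ndarray
    pixel_area: float = 1.0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)

    @property
    def size_km2(self) -> float:
        return self.n_cells * self.pixel_area

    def cell_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass
class ClimateCube:
    """Annual growing-season temperature (°C) and precipitation (mm) grids."""

    tas: np.ndarray  # (n_years, n_rows, n_cols)
    pr: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.tas = np.asarray(self.tas, dtype=np.float64)
        self.pr = np.asarray(self.pr, dtype=np.float64)
        if self.tas.shape != self.pr.shape or self.tas.ndim != 3:
            raise ValueError("tas and pr must be (year, row, col) and congruent")

    @property
    def n_years(self) -> int:
        return self.tas.shape[0]

    def year(self, year_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Climate fields for 1-based simulation year ``year_index``."""
        return self.tas[year_index - 1], self.pr[year_index - 1]


@dataclass
class RangeMask:
    """Named boolean mask delimiting one herd's winter range."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"range mask {self.name!r} has no true pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class HistoricalFireRecord:
    """Year-stamped burn masks with per-fire integer labels.

    ``fire_labels`` is zero outside burns; within a year, each fire is one
    8-connected component with a distinct positive id.
    """

    years: list[int]
    burn_masks: np.ndarray  # (n_years, n_rows, n_cols) bool
    fire_labels: np.ndarray  # (n_years, n_rows, n_cols) int32
    pixel_area: float = 1.0

    def __post_init__(self) -> None:
        self.burn_masks = np.asarray(self.burn_masks, dtype=bool)
        self.fire_labels = np.asarray(self.fire_labels, dtype=np.int32)
        if self.burn_masks.shape != self.fire_labels.shape:
            raise ValueError("burn masks and fire labels must share shape")
        if len(self.years) != self.burn_masks.shape[0]:
            raise ValueError("one burn mask per year required")
        if not np.array_equal(self.fire_labels > 0, self.burn_masks):
            raise ValueError("fire labels must be nonzero exactly on burned pixels")


@dataclass
class RunEnsemble:
    """Replicate simulations: burn masks, annual snapshots and fire lists.

    ``burn``, ``veg`` and ``age`` are indexed ``(run, year, row, col)``
    with year 0-based internally (simulation year ``y`` is index ``y-1``).
    ``veg``/``age`` are the start-of-year states, i.e. the landscape the
    fires of that year ignited on.  ``fires[run][year_index]`` is the list
    of that run-year's FireEvents.
    """

    burn: np.ndarray
    veg: np.ndarray
    age: np.ndarray
    fires: list[list[list[FireEvent]]]
    pixel_area: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.burn = np.asarray(self.burn, dtype=bool)
        if self.burn.ndim != 4:
            raise ValueError("burn store must be (run, year, row, col)")

    @property
    def n_runs(self) -> int:
        return self.burn.shape[0]

    @property
    def n_years(self) -> int:
        return self.burn.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.burn.shape[2], self.burn.shape[3]

    def area_burned_matrix(self) -> np.ndarray:
        """Annual area burned (km²) per run: shape (n_runs, n_years)."""
        return self.burn.sum(axis=(2, 3)).astype(float) * self.pixel_area
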