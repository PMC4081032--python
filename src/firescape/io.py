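"""Raster and tabular persistence for the simulation pipeline.

Grids are written as single-band TIFF (nodata −1) with a synthetic affine
transform recorded in a JSON sidecar; climate cubes as NetCDF (dims year,
row, col; variables ``tas_gs``, ``pr_gs``); fire catalogs, regime stats
and habitat series as tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .types import (
    ClimateCube,
    HistoricalFireRecord,
    LandscapeState,
    RangeMask,
    RunEnsemble,
    year_to_label,
)

NODATA = -1

#: placeholder affine transform: 1-km pixels anchored at a synthetic origin
SYNTHETIC_TRANSFORM = {"origin": [0.0, 0.0], "pixel_size_km": 1.0, "crs": "synthetic"}


def _write_grid(path: Path, grid: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(grid))


def save_landscape(state: LandscapeState, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_grid(out / "veg.tif", state.veg.astype(np.int16))
    _write_grid(out / "age.tif", state.age.astype(np.int32))
    meta = {
        "year": state.year,
        "pixel_area_km2": state.pixel_area,
        "nodata": NODATA,
        "transform": SYNTHETIC_TRANSFORM,
    }
    (out / "landscape.json").write_text(json.dumps(meta, indent=2))
    return out


def load_landscape(in_dir: str | Path) -> LandscapeState:
    d = Path(in_dir)
    meta = json.loads((d / "landscape.json").read_text())
    return LandscapeState(
        veg=tifffile.imread(str(d / "veg.tif")),
        age=tifffile.imread(str(d / "age.tif")),
        year=meta["year"],
        pixel_area=meta["pixel_area_km2"],
    )


def save_climate(cube: ClimateCube, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_years = cube.n_years
    ds = xr.Dataset(
        {
            "tas_gs": (("year", "row", "col"), cube.tas),
            "pr_gs": (("year", "row", "col"), cube.pr),
        },
        coords={"year": [year_to_label(y) for y in range(1, n_years + 1)]},
        attrs={"scenario": cube.label},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def load_climate(path: str | Path) -> ClimateCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ClimateCube(
            tas=ds["tas_gs"].values.copy(),
            pr=ds["pr_gs"].values.copy(),
            label=str(ds.attrs.get("scenario", "")),
        )


def save_range_masks(masks: list[RangeMask], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rm in masks:
        _write_grid(out / f"range_{rm.name}.tif", rm.mask.astype(np.uint8))
    (out / "ranges.json").write_text(
        json.dumps({"names": [rm.name for rm in masks]}, indent=2)
    )
    return out


def load_range_masks(in_dir: str | Path) -> list[RangeMask]:
    d = Path(in_dir)
    names = json.loads((d / "ranges.json").read_text())["names"]
    return [
        RangeMask(name=n, mask=tifffile.imread(str(d / f"range_{n}.tif")) > 0)
        for n in names
    ]


def save_fire_record(record: HistoricalFireRecord, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_grid(out / "fire_labels.tif", record.fire_labels)
    rows = []
    for yi, year in enumerate(record.years):
        labels = record.fire_labels[yi]
        for fid in np.unique(labels[labels > 0]):
            rows.append(
                {"year": year, "fire_id": int(fid),
                 "size_km2": float((labels == fid).sum()) * record.pixel_area}
            )
    pd.DataFrame(rows, columns=["year", "fire_id", "size_km2"]).to_csv(
        out / "fire_index.csv", index=False
    )
    meta = {"years": record.years, "pixel_area_km2": record.pixel_area,
            "transform": SYNTHETIC_TRANSFORM}
    (out / "record.json").write_text(json.dumps(meta, indent=2))
    return out


def load_fire_record(in_dir: str | Path) -> HistoricalFireRecord:
    d = Path(in_dir)
    meta = json.loads((d / "record.json").read_text())
    labels = tifffile.imread(str(d / "fire_labels.tif"))
    if labels.ndim == 2:
        labels = labels[None]
    return HistoricalFireRecord(
        years=list(meta["years"]),
        burn_masks=labels > 0,
        fire_labels=labels,
        pixel_area=meta["pixel_area_km2"],
    )


def save_ensemble(ensemble: RunEnsemble, out_dir: str | Path) -> Path:
    """Persist an ensemble: burn/veg/age stacks plus a fire-catalog CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "ensemble.npz",
        burn=ensemble.burn, veg=ensemble.veg, age=ensemble.age,
    )
    rows = []
    for run, run_fires in enumerate(ensemble.fires):
        for yi, year_fires in enumerate(run_fires):
            for fid, fire in enumerate(year_fires, start=1):
                rows.append(
                    {"run": run, "year": year_to_label(yi + 1), "fire_id": fid,
                     "ignition_row": fire.ignition[0],
                     "ignition_col": fire.ignition[1],
                     "size_km2": fire.size_km2}
                )
    pd.DataFrame(
        rows,
        columns=["run", "year", "fire_id", "ignition_row", "ignition_col",
                 "size_km2"],
    ).to_csv(out / "fire_catalog.csv", index=False)
    meta = {"pixel_area_km2": ensemble.pixel_area, "label": ensemble.label,
            "n_runs": ensemble.n_runs, "n_years": ensemble.n_years}
    (out / "ensemble.json").write_text(json.dumps(meta, indent=2))
    return out


def load_ensemble(in_dir: str | Path) -> RunEnsemble:
    """Load ensemble stacks; the fire catalog is reattached as cell-less
    events only via the CSV (burn masks remain authoritative)."""
    d = Path(in_dir)
    meta = json.loads((d / "ensemble.json").read_text())
    with np.load(d / "ensemble.npz") as data:
        burn, veg, age = data["burn"], data["veg"], data["age"]
    fires: list[list[list]] = [
        [[] for _ in range(meta["n_years"])] for _ in range(meta["n_runs"])
    ]
    return RunEnsemble(
        burn=burn, veg=veg, age=age, fires=fires,
        pixel_area=meta["pixel_area_km2"], label=meta["label"],
    )
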