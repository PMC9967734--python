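"""Minimal raster container and plain-text grid I/O.

Rasters are stored row-major with the origin at the top-left corner, in a
projected coordinate system measured in metres.  Categorical land-use grids
use integer codes 1-6 with 0 as nodata; continuous driver grids are float32
with NaN as nodata.  On disk we use the ESRI ASCII grid format, which every
desktop GIS reads, with an optional JSON sidecar recording provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: land-use class codes
CULTIVATED, FOREST, GRASSLAND, WATER, CONSTRUCTION, UNUTILIZED = range(1, 7)
CLASS_CODES = (CULTIVATED, FOREST, GRASSLAND, WATER, CONSTRUCTION, UNUTILIZED)
CLASS_NAMES = {
    CULTIVATED: "cultivated",
    FOREST: "forest",
    GRASSLAND: "grassland",
    WATER: "water",
    CONSTRUCTION: "construction",
    UNUTILIZED: "unutilized",
}
#: classes counted as green space: cultivated, forest, grassland, water
GREEN_CLASSES = frozenset({CULTIVATED, FOREST, GRASSLAND, WATER})
N_CLASSES = 6


@dataclass
class Raster:
    """A single-band raster with top-left origin.

    Parameters
    ----------
    values
        2-D array, shape ``(n_rows, n_cols)``.
    cell_size_m
        Side length of a (square) cell in metres.
    x0, y0
        Coordinates of the top-left corner of the top-left cell.
    nodata
        Sentinel for missing cells (0 for categorical, NaN for float grids).
    """

    values: np.ndarray
    cell_size_m: float = 1000.0
    x0: float = 0.0
    y0: float = 0.0
    nodata: float = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_size_m / 100.0) ** 2

    def valid_mask(self) -> np.ndarray:
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def n_valid(self) -> int:
        return int(self.valid_mask().sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centres, shape = raster."""
        nr, nc = self.shape
        xs = self.x0 + (np.arange(nc) + 0.5) * self.cell_size_m
        ys = self.y0 - (np.arange(nr) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def like(self, values: np.ndarray, nodata=None) -> "Raster":
        """New raster sharing this raster's grid geometry."""
        return replace(self, values=values,
                       nodata=self.nodata if nodata is None else nodata)

    def check_aligned(self, other: "Raster") -> None:
        if self.shape != other.shape:
            raise ValueError(
                f"raster shape mismatch: {self.shape} vs {other.shape}")

    # -- class bookkeeping ----------------------------------------------
    def class_counts(self) -> np.ndarray:
        """Cell count per land-use class (length 6, classes 1..6)."""
        v = self.values[self.valid_mask()].astype(int)
        return np.bincount(v, minlength=N_CLASSES + 1)[1:N_CLASSES + 1]


def write_ascii_grid(raster: Raster, path: str | Path,
                     fmt: str = "%.6g", sidecar: dict | None = None) -> None:
    """Write an ESRI ASCII grid (plus optional JSON sidecar)."""
    path = Path(path)
    nr, nc = raster.shape
    nodata = raster.nodata
    vals = raster.values
    if isinstance(nodata, float) and np.isnan(nodata):
        nodata = -9999
        vals = np.where(np.isnan(raster.values), nodata, raster.values)
    header = (
        f"ncols {nc}\nnrows {nr}\n"
        f"xllcorner {raster.x0}\n"
        f"yllcorner {raster.y0 - nr * raster.cell_size_m}\n"
        f"cellsize {raster.cell_size_m}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2,
                                                        default=str))


def read_ascii_grid(path: str | Path, dtype=float) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=dtype)
    values = np.atleast_2d(values)
    nr = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999)
    if dtype is not float and float(nodata) == int(nodata):
        nodata = int(nodata)
    return Raster(values, cell_size_m=cell, x0=header["xllcorner"],
                  y0=header["yllcorner"] + nr * cell, nodata=nodata)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
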