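"""Ecosystem carbon bookkeeping from land-use class densities.

Each land-use class carries a fixed carbon density (t/ha) that is the sum
of four pools: above-ground biomass, below-ground biomass, soil organic
carbon and dead organic matter.  A cell's stock is its class density times
its area in hectares; regional totals are straight sums.  This is the
standard lookup-table carbon accounting used for rapid land-change
assessments: it responds to class transitions only, not to within-class
variation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .greenspace import EVOLUTION_NAMES, EvolutionMap, classify_green
from .raster import CLASS_CODES, CLASS_NAMES, N_CLASSES, Raster

POOLS = ("above", "below", "soil", "dead")

# default densities (t/ha) for a cold-temperate black-soil province,
# compiled from regional field studies
_DEFAULT_DENSITY_CSV = """\
class,above,below,soil,dead
cultivated,10.1,26.8,147,0
forest,11.46,31.32,173.9,2.02
grassland,7.96,51,74.6,2.84
water,8.72,2.21,23.01,0
construction,8.75,4.39,27.78,1.16
unutilized,10.03,0,44.79,0
"""

_NAME_TO_CODE = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class CarbonDensityTable:
    """Per-class carbon pool densities in t/ha."""

    table: pd.DataFrame   # index: class code 1..6, columns: the four pools

    def __post_init__(self) -> None:
        missing = [p for p in POOLS if p not in self.table.columns]
        if missing:
            raise ValueError(f"density table missing pools {missing}")
        if (self.table[list(POOLS)] < 0).any().any():
            raise ValueError("carbon densities must be non-negative")

    @classmethod
    def default(cls) -> "CarbonDensityTable":
        return cls.from_csv(io.StringIO(_DEFAULT_DENSITY_CSV))

    @classmethod
    def from_csv(cls, path) -> "CarbonDensityTable":
        df = pd.read_csv(path)
        if "class" in df.columns:
            df["class"] = [
                _NAME_TO_CODE.get(str(c).strip().lower(), c)
                for c in df["class"]
            ]
            df = df.set_index("class")
        df.index = df.index.astype(int)
        return cls(df[list(POOLS)].astype(float))

    def total_density(self, cls: int) -> float:
        """Total carbon density of a class: the sum of its four pools."""
        if cls not in self.table.index:
            raise KeyError(f"class {cls} not in density table")
        return float(self.table.loc[cls, list(POOLS)].sum())

    def density_vector(self) -> np.ndarray:
        """Total density per class code 1..6 (t/ha)."""
        return np.array([self.total_density(c) for c in CLASS_CODES])


def class_total_density(table: CarbonDensityTable, cls: int) -> float:
    return table.total_density(cls)


@dataclass
class CarbonMap:
    """Per-cell carbon stock (t) with its class- and grid-level totals."""

    stock: Raster                     # tonnes per cell, NaN = nodata
    total_t: float
    by_class_t: pd.Series


def carbon_map(landuse: Raster, table: CarbonDensityTable) -> CarbonMap:
    """Per-cell carbon stock: class density (t/ha) x cell area (ha)."""
    area_ha = landuse.cell_area_ha
    valid = landuse.valid_mask()
    dens = np.full(N_CLASSES + 1, np.nan)
    for c in CLASS_CODES:
        dens[c] = table.total_density(c)
    vals = landuse.values.astype(int)
    stock = np.where(valid, dens[np.clip(vals, 0, N_CLASSES)] * area_ha,
                     np.nan)
    by_class = pd.Series(
        {CLASS_NAMES[c]: float(stock[valid & (vals == c)].sum())
         for c in CLASS_CODES}, name="carbon_t")
    return CarbonMap(landuse.like(stock, nodata=np.nan),
                     total_t=float(np.nansum(stock)), by_class_t=by_class)


def masked_green_total(landuse: Raster, table: CarbonDensityTable) -> float:
    """Total carbon (t) over the epoch's own green-space mask."""
    cm = carbon_map(landuse, table)
    green = classify_green(landuse).values == 1
    return float(np.nansum(np.where(green, cm.stock.values, 0.0)))


def carbon_change(cm_t0: CarbonMap, cm_t1: CarbonMap,
                  evo: EvolutionMap) -> tuple[Raster, pd.Series]:
    """Per-cell carbon change (t) and totals per evolution type."""
    cm_t0.stock.check_aligned(cm_t1.stock)
    cm_t0.stock.check_aligned(evo.labels)
    delta = cm_t1.stock.values - cm_t0.stock.values
    labels = evo.labels.values
    totals = pd.Series(
        {name: float(np.nansum(np.where(labels == code, delta, 0.0)))
         for code, name in EVOLUTION_NAMES.items()},
        name="delta_carbon_t")
    return cm_t0.stock.like(delta, nodata=np.nan), totals


def prevented_carbon_loss(loss_np: float, loss_bcu: float) -> float:
    """Carbon loss avoided by the conservation scenario (same units in/out).

    Both arguments are carbon *losses* (positive magnitudes); the result is
    their difference, the loss the policy eliminates.
    """
    return loss_np - loss_bcu
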