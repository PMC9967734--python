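"""Green-space classification and evolution typing between two epochs.

Green space is the union of cultivated land, forest, grassland and water;
construction and unutilized land are non-green.  Between two epochs each
cell is typed as stable (green or non-green), expansion (non-green to
green), exchange (green to a different green class) or loss (green to
non-green).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GREEN_CLASSES, Raster

# evolution codes
STABLE_GREEN, STABLE_NONGREEN, EXPANSION, EXCHANGE, LOSS = range(1, 6)
EVOLUTION_NAMES = {
    STABLE_GREEN: "stable_green",
    STABLE_NONGREEN: "stable_nongreen",
    EXPANSION: "expansion",
    EXCHANGE: "exchange",
    LOSS: "loss",
}


@dataclass
class EvolutionMap:
    """Per-cell evolution label raster (codes above, 0 = nodata)."""

    labels: Raster

    @property
    def cell_area_km2(self) -> float:
        return self.labels.cell_area_km2

    def counts(self) -> pd.Series:
        vals = self.labels.values[self.labels.valid_mask()]
        return pd.Series(
            {name: int((vals == code).sum())
             for code, name in EVOLUTION_NAMES.items()}, name="cells")


def classify_green(landuse: Raster) -> Raster:
    """Binary green-space raster: 1 = green, 0 = non-green, nodata kept."""
    valid = landuse.valid_mask()
    vals = landuse.values
    known = np.isin(vals[valid], range(1, 7))
    if not known.all():
        bad = np.unique(vals[valid][~known])
        raise ValueError(f"unknown land-use codes {bad.tolist()}")
    green = np.isin(vals, tuple(GREEN_CLASSES)) & valid
    out = np.where(valid, green.astype(np.int8), -1)
    return landuse.like(out, nodata=-1)


def evolution_type(map_t0: Raster, map_t1: Raster) -> EvolutionMap:
    """Type every cell's green-space trajectory between two epochs."""
    map_t0.check_aligned(map_t1)
    g0 = classify_green(map_t0)
    g1 = classify_green(map_t1)
    valid = g0.valid_mask() & g1.valid_mask()
    green0 = g0.values == 1
    green1 = g1.values == 1
    same_class = map_t0.values == map_t1.values

    labels = np.zeros(map_t0.shape, dtype=np.int8)
    labels[valid & green0 & ~green1] = LOSS
    labels[valid & ~green0 & green1] = EXPANSION
    labels[valid & green0 & green1 & ~same_class] = EXCHANGE
    labels[valid & green0 & green1 & same_class] = STABLE_GREEN
    labels[valid & ~green0 & ~green1] = STABLE_NONGREEN
    return EvolutionMap(map_t0.like(labels, nodata=0))


def tabulate_evolution(evo: EvolutionMap) -> pd.Series:
    """Areas (km^2) of the expansion / exchange / loss evolution types."""
    counts = evo.counts()
    area = counts * evo.cell_area_km2
    return area.loc[["expansion", "exchange", "loss"]].rename("area_km2")


def prevented_net_loss(table_np: pd.Series, table_bcu: pd.Series) -> float:
    """Net green-space loss avoided by the conservation scenario (km^2).

    Net loss of a scenario is loss minus expansion; the prevented amount is
    the NP net loss minus the BCU net loss.
    """
    net_np = float(table_np["loss"]) - float(table_np["expansion"])
    net_bcu = float(table_bcu["loss"]) - float(table_bcu["expansion"])
    return net_np - net_bcu
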