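"""Seeded synthetic landscapes with known statistical structure.

The generator produces everything the downstream analysis consumes: a
spatially autocorrelated categorical land-cover grid with prescribed class
proportions, a second epoch evolved from a known ground-truth transition
matrix, nine continuous driver surfaces (terrain, climate, socio-economic,
road distances) and a contiguous black-soil mask.  Because the true
transition matrix and class proportions are known, every estimator further
down the pipeline can be checked for parameter recovery.

The categorical field is built by thresholding a Gaussian-smoothed white
noise field at the quantiles implied by the class proportions, which gives
controllable spatial autocorrelation with exact marginal control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .raster import (CLASS_CODES, N_CLASSES, Raster, write_ascii_grid)

DEFAULT_PROPORTIONS = (0.38, 0.34, 0.08, 0.04, 0.10, 0.06)
#: default per-period dynamics: persistent classes with agricultural
#: expansion (inflow to cultivated from forest/grassland/unutilized),
#: construction growth, and retreat of forest and unutilized land, so all
#: three green-space evolution types (expansion/exchange/loss) occur
DEFAULT_TRANSITIONS = (
    (0.92, 0.02, 0.01, 0.00, 0.04, 0.01),
    (0.10, 0.86, 0.02, 0.00, 0.01, 0.01),
    (0.12, 0.04, 0.80, 0.01, 0.02, 0.01),
    (0.02, 0.01, 0.01, 0.95, 0.01, 0.00),
    (0.01, 0.00, 0.00, 0.00, 0.98, 0.01),
    (0.20, 0.06, 0.04, 0.01, 0.04, 0.65),
)

DRIVER_NAMES = (
    "elevation", "slope", "temperature", "precipitation",
    "population", "gdp", "dist_national", "dist_provincial", "dist_highway",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study region.

    Defaults describe a 300 x 300 cell landscape at 1 km resolution --
    the working desk scale of the package -- with a cultivated/forest
    dominated class mix and moderate spatial autocorrelation.
    """

    n_rows: int = 300
    n_cols: int = 300
    cell_size_m: float = 1000.0
    class_proportions: tuple = DEFAULT_PROPORTIONS
    autocorr_range_cells: float = 6.0
    true_transition_matrix: tuple = DEFAULT_TRANSITIONS
    seed: int = 0
    blacksoil_fraction: float = 0.25
    driver_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (N_CLASSES,):
            raise ValueError("class_proportions must have 6 entries")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be >= 0 and sum to 1")
        m = np.asarray(self.true_transition_matrix, dtype=float)
        if m.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("true_transition_matrix must be 6x6")
        if (m < 0).any() or np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition matrix rows must be stochastic")
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.autocorr_range_cells <= 0:
            raise ValueError("autocorr_range_cells must be positive")
        if not 0.0 <= self.blacksoil_fraction <= 1.0:
            raise ValueError("blacksoil_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "cell_size_m": self.cell_size_m,
            "class_proportions": list(self.class_proportions),
            "autocorr_range_cells": self.autocorr_range_cells,
            "true_transition_matrix":
                [list(r) for r in self.true_transition_matrix],
            "seed": self.seed,
            "blacksoil_fraction": self.blacksoil_fraction,
            "driver_noise_sd": self.driver_noise_sd,
        }


@dataclass
class DriverStack:
    """Continuous driver surfaces plus the black-soil policy mask."""

    layers: dict
    blacksoil: Raster = None

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian white noise convolved with a Gaussian kernel, unit-free."""
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")


def generate_base_landscape(config: SyntheticConfig) -> Raster:
    """Autocorrelated categorical land cover with prescribed proportions.

    A smoothed Gaussian random field is thresholded at the quantiles
    implied by ``class_proportions``: the lowest ``p1`` fraction of cells
    becomes class 1, the next ``p2`` class 2, and so on.  The rank
    transform makes the empirical class proportions exact up to grid
    granularity while the smoothing yields contiguous patches.
    """
    rng = np.random.default_rng(config.seed)
    f = _smooth_field(rng, (config.n_rows, config.n_cols),
                      config.autocorr_range_cells)
    # rank the field so quantile thresholds are exact
    order = np.argsort(f, axis=None, kind="stable")
    n = f.size
    cum = np.cumsum(config.class_proportions)
    bounds = np.round(cum * n).astype(int)
    codes = np.empty(n, dtype=np.int16)
    start = 0
    for cls, stop in zip(CLASS_CODES, bounds):
        codes[order[start:stop]] = cls
        start = stop
    codes[order[start:]] = CLASS_CODES[-1]  # rounding remainder
    return Raster(codes.reshape(f.shape), cell_size_m=config.cell_size_m,
                  y0=config.n_rows * config.cell_size_m, nodata=0)


def _random_polyline_mask(rng: np.random.Generator, shape) -> np.ndarray:
    """Boolean mask of a few random straight road segments."""
    nr, nc = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(2, 5)):
        r0, r1 = rng.integers(0, nr, size=2)
        c0, c1 = rng.integers(0, nc, size=2)
        n = max(abs(int(r1) - int(r0)), abs(int(c1) - int(c0)), 1) * 2
        rr = np.round(np.linspace(r0, r1, n)).astype(int)
        cc = np.round(np.linspace(c0, c1, n)).astype(int)
        mask[rr, cc] = True
    return mask


def _distance_to(mask: np.ndarray, cell_size_m: float) -> np.ndarray:
    return ndimage.distance_transform_edt(~mask) * cell_size_m


def slope_degrees(elevation: Raster) -> Raster:
    """Slope in degrees from central finite differences of the elevation."""
    dz_dy, dz_dx = np.gradient(elevation.values, elevation.cell_size_m)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    return elevation.like(slope, nodata=np.nan)

def generate_blacksoil_mask(config: SyntheticConfig,
                            rng: np.random.Generator) -> Raster:
    """Contiguous black-soil region covering ``blacksoil_fraction`` of cells.

    The region is the set of cells nearest (Euclidean) to a random centre,
    which is contiguous by construction and hits the target fraction to
    within one cell.
    """
    nr, nc = config.n_rows, config.n_cols
    n_target = int(round(config.blacksoil_fraction * nr * nc))
    cy, cx = rng.uniform(0, nr), rng.uniform(0, nc)
    yy, xx = np.mgrid[0:nr, 0:nc]
    dist = np.hypot(yy + 0.5 - cy, xx + 0.5 - cx)
    mask = np.zeros((nr, nc), dtype=np.int8)
    if n_target > 0:
        flat = np.argsort(dist, axis=None, kind="stable")[:n_target]
        mask.flat[flat] = 1
    return Raster(mask, cell_size_m=config.cell_size_m,
                  y0=nr * config.cell_size_m, nodata=-1)


def generate_drivers(config: SyntheticConfig, base: Raster) -> DriverStack:
    """Nine driver surfaces with the roles the suitability model expects.

    Elevation, temperature and precipitation are independent smooth random
    fields; slope is derived from elevation by finite differences; road
    distances are Euclidean distance transforms from random polylines.
    Population density and GDP are smooth fields amplified (x3 mean) inside
    a randomly placed urban disc so construction suitability has a signal
    to respond to.  A derived seed keeps drivers independent of the
    land-cover draw.
    """
    rng = np.random.default_rng((config.seed * 7919 + 17) % (2**31))
    shape = (config.n_rows, config.n_cols)
    sd = config.driver_noise_sd
    cell = config.cell_size_m

    def raster(vals):
        return Raster(np.asarray(vals, dtype=np.float64), cell_size_m=cell,
                      y0=config.n_rows * cell, nodata=np.nan)

    # rough terrain: short-range relief on top of a long-range trend so a
    # tail of cells exceeds the 15 degree policy threshold at 1 km cells
    relief = _smooth_field(rng, shape, sigma=1.5)
    trend = _smooth_field(rng, shape, sigma=max(8.0, min(shape) / 8))
    elev_raw = 3.0 * trend + relief
    elev = raster(1200.0 * (elev_raw - elev_raw.min())
                  / max(np.ptp(elev_raw), 1e-12) * sd + 150.0)
    slope = slope_degrees(elev)

    temp = raster(2.5 * sd * _smooth_field(rng, shape, sigma=10) + 2.0)
    precip = raster(np.clip(
        80 * sd * _smooth_field(rng, shape, sigma=10) + 520, 0, None))

    pop = np.exp(_smooth_field(rng, shape, sigma=5) * sd)
    gdp = np.exp(_smooth_field(rng, shape, sigma=5) * sd)
    # urban disc: elevate population and GDP around a random centre
    cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    disc = np.hypot(yy - cy, xx - cx) <= min(shape) / 6
    pop[disc] *= 3.0
    gdp[disc] *= 3.0

    dists = {}
    for name in ("dist_national", "dist_provincial", "dist_highway"):
        dists[name] = raster(_distance_to(
            _random_polyline_mask(rng, shape), cell))

    layers = {
        "elevation": elev, "slope": slope, "temperature": temp,
        "precipitation": precip, "population": raster(pop),
        "gdp": raster(gdp), **dists,
    }
    return DriverStack(layers=layers,
                       blacksoil=generate_blacksoil_mask(config, rng))


def evolve_landscape(base: Raster, config: SyntheticConfig) -> Raster:
    """Second-epoch land cover from per-cell multinomial transitions.

    Each valid cell of class ``i`` draws its new class from row ``i`` of
    ``true_transition_matrix``.  Cells are independent given the base map,
    so the empirical transition matrix converges to the truth.
    """
    rng = np.random.default_rng((config.seed * 104729 + 389) % (2**31))
    P = np.asarray(config.true_transition_matrix, dtype=float)
    out = np.array(base.values, dtype=np.int16, copy=True)
    for i, cls in enumerate(CLASS_CODES):
        sel = base.values == cls
        k = int(sel.sum())
        if k:
            out[sel] = rng.choice(CLASS_CODES, size=k, p=P[i])
    return base.like(out)


def write_stack(directory: str | Path, base: Raster, epoch2: Raster,
                drivers: DriverStack, config: SyntheticConfig) -> None:
    """Write all synthetic layers as ASCII grids with a config sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {"config": config.to_dict()}
    write_ascii_grid(base, directory / "landuse_t0.asc", fmt="%d",
                     sidecar=sidecar)
    write_ascii_grid(epoch2, directory / "landuse_t1.asc", fmt="%d")
    for name, layer in drivers.layers.items():
        write_ascii_grid(layer, directory / f"{name}.asc")
    write_ascii_grid(drivers.blacksoil, directory / "blacksoil.asc", fmt="%d")
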