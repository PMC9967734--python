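"""Grid-based landscape ecological risk assessment.

The study extent is partitioned into square sampling plots (default
20 km x 20 km).  Within each plot, per-class landscape structure indices
are computed from patch statistics:

* fragmentation  ``C_i = n_i / A_i``
* separation     ``S_i = (A / (2 A_i)) * sqrt(n_i / A)``
* dominance      ``K_i = 1/4 (n_i/N + m_i/M) + 1/2 (A_i/A)``
* disturbance    ``I_i = 0.5 C_i + 0.3 S_i + 0.2 K_i``

where ``n_i`` and ``A_i`` are the plot's patch count and area of class i,
and ``A`` (total plot area), ``N`` (total patches), ``M`` (number of
plots) and ``m_i`` (plots where class i occurs) are grid-wide totals.
Combining disturbance with a fixed per-class vulnerability ``E_i`` gives
the loss index ``R_i = I_i * E_i`` and the plot's ecological risk index

    ``ERI = sum_i (A_i / A_n) * R_i``

with ``A_n`` the plot area.  Plot-centroid ERI values are interpolated to
a continuous surface by ordinary kriging (spherical variogram, weighted
least-squares fit) and classified into five bands, either at fixed
thresholds or by Jenks natural breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from shapely.geometry import box

from .raster import (CLASS_CODES, CLASS_NAMES, CONSTRUCTION, CULTIVATED,
                     FOREST, GRASSLAND, N_CLASSES, UNUTILIZED, WATER, Raster)

__all__ = [
    "RiskGrid", "RiskSurface", "make_grid", "patch_statistics",
    "landscape_indices", "vulnerability", "eri", "compute_risk_grid",
    "interpolate_surface", "classify_risk", "jenks_breaks",
    "PAPER_RISK_BREAKS", "VULNERABILITY_RANKS",
]

#: five-band classification thresholds used for reporting
PAPER_RISK_BREAKS = (0.010, 0.012, 0.013, 0.015)
RISK_BAND_NAMES = {1: "low", 2: "lower", 3: "medium", 4: "higher", 5: "high"}

#: vulnerability ranking, least to most fragile:
#: built-up < water < grassland < forest < unused < cropland
VULNERABILITY_RANKS = {
    CONSTRUCTION: 1, WATER: 2, GRASSLAND: 3,
    FOREST: 4, UNUTILIZED: 5, CULTIVATED: 6,
}

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class RiskGrid:
    """Square sampling plots over a raster extent.

    ``table`` holds one row per retained plot (id, row/col block, centroid
    coordinates, valid area); index columns are attached by
    :func:`compute_risk_grid`.
    """

    table: pd.DataFrame
    plot_size_cells: int
    template: Raster          # geometry reference (the source raster)
    n_grid_rows: int
    n_grid_cols: int

    def __len__(self) -> int:
        return len(self.table)

    def plot_slices(self, row) -> tuple[slice, slice]:
        r0, c0 = int(row.block_row) * self.plot_size_cells, \
            int(row.block_col) * self.plot_size_cells
        nr, nc = self.template.shape
        return (slice(r0, min(r0 + self.plot_size_cells, nr)),
                slice(c0, min(c0 + self.plot_size_cells, nc)))

    def to_geojson(self) -> dict:
        feats = []
        half = self.plot_size_cells * self.template.cell_size_m
        for _, row in self.table.iterrows():
            r0, c0 = row.block_row * half, row.block_col * half
            x0 = self.template.x0 + row.block_col * half
            y1 = self.template.y0 - row.block_row * half
            poly = box(x0, y1 - half, x0 + half, y1)
            props = {k: (v if isinstance(v, str) else float(v))
                     for k, v in row.items()}
            feats.append({"type": "Feature", "properties": props,
                          "geometry": poly.__geo_interface__})
        return {"type": "FeatureCollection", "features": feats}


@dataclass
class RiskSurface:
    """Interpolated ERI surface plus its five-band classification."""

    eri: Raster
    bands: Raster | None = None
    breaks: tuple | None = None
    method: str = "ordinary_kriging"


def make_grid(landuse: Raster, cell_km: float = 20.0,
              min_valid_fraction: float = 0.1) -> RiskGrid:
    """Partition the raster into square plots of side ``cell_km``.

    Plots with less than ``min_valid_fraction`` valid cells are dropped;
    an all-nodata raster raises.
    """
    size = int(round(cell_km * 1000.0 / landuse.cell_size_m))
    if size < 1:
        raise ValueError("plot size below one raster cell")
    nr, nc = landuse.shape
    if nr < size and nc < size:
        # a single partial plot is still allowed as long as data exist
        pass
    valid = landuse.valid_mask()
    n_grid_rows = int(np.ceil(nr / size))
    n_grid_cols = int(np.ceil(nc / size))
    rows = []
    pid = 0
    for br in range(n_grid_rows):
        for bc in range(n_grid_cols):
            block = valid[br * size:(br + 1) * size,
                          bc * size:(bc + 1) * size]
            frac = block.mean() if block.size else 0.0
            if frac < min_valid_fraction:
                continue
            cx = landuse.x0 + (bc + 0.5) * size * landuse.cell_size_m
            cy = landuse.y0 - (br + 0.5) * size * landuse.cell_size_m
            rows.append({"plot_id": pid, "block_row": br, "block_col": bc,
                         "centroid_x": cx, "centroid_y": cy,
                         "valid_cells": int(block.sum()),
                         "area_km2": block.sum() * landuse.cell_area_km2})
            pid += 1
    if not rows:
        raise ValueError("no plots contain valid data")
    return RiskGrid(pd.DataFrame(rows), size, landuse,
                    n_grid_rows, n_grid_cols)


def patch_statistics(landuse: Raster, grid: RiskGrid) -> dict:
    """Patch counts and areas per plot and class, plus grid-wide totals.

    Patches are 8-connected components of same-class cells *within* a
    plot.  Returns a dict with arrays ``n`` and ``area`` of shape
    (n_plots, 6), plot areas ``A_n``, and scalars/vectors ``N``, ``M``,
    ``m`` and total area ``A`` over the retained plots.
    """
    n_plots = len(grid)
    n = np.zeros((n_plots, N_CLASSES), dtype=int)
    area = np.zeros((n_plots, N_CLASSES), dtype=float)
    cell_area = landuse.cell_area_km2
    valid = landuse.valid_mask()
    for k, row in enumerate(grid.table.itertuples()):
        rs, cs = grid.plot_slices(row)
        block = np.where(valid[rs, cs], landuse.values[rs, cs], 0)
        for j, cls in enumerate(CLASS_CODES):
            m_cls = block == cls
            if not m_cls.any():
                continue
            _, n_comp = ndimage.label(m_cls, structure=_EIGHT_CONN)
            n[k, j] = n_comp
            area[k, j] = m_cls.sum() * cell_area
    return {
        "n": n, "area": area,
        "A_n": grid.table["area_km2"].to_numpy(),
        "N": int(n.sum()),
        "M": n_plots,
        "m": (area > 0).sum(axis=0),          # plots where class occurs
        "A": float(area.sum()),
    }


def landscape_indices(stats: dict, a: float = 0.5, b: float = 0.3,
                      c: float = 0.2) -> dict:
    """Fragmentation, separation, dominance and disturbance per plot/class.

    Entries for classes absent from a plot (A_i = 0) are NaN.
    """
    n = stats["n"].astype(float)
    A_i = stats["area"]
    A, N, M = stats["A"], stats["N"], stats["M"]
    m = stats["m"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(A_i > 0, n / A_i, np.nan)
        S = np.where(A_i > 0, (A / (2.0 * A_i)) * np.sqrt(n / A), np.nan)
        K = np.where(A_i > 0,
                     0.25 * (n / max(N, 1) + m[None, :] / M)
                     + 0.5 * (A_i / A), np.nan)
    I = a * C + b * S + c * K
    return {"C": C, "S": S, "K": K, "I": I}


def vulnerability(cls: int | None = None):
    """Normalized landscape vulnerability E_i = rank / sum(ranks).

    Ranks order the six classes from least to most fragile; the sum of
    ranks is 21, so e.g. cropland (rank 6) has E = 6/21 = 0.286.
    """
    total = sum(VULNERABILITY_RANKS.values())
    if cls is not None:
        if cls not in VULNERABILITY_RANKS:
            raise KeyError(f"unknown class {cls}")
        return VULNERABILITY_RANKS[cls] / total
    return np.array([VULNERABILITY_RANKS[c] / total for c in CLASS_CODES])


def eri(stats: dict, indices: dict | None = None) -> np.ndarray:
    """Ecological risk index per plot: ERI = sum_i (A_i/A_n) * I_i * E_i."""
    if indices is None:
        indices = landscape_indices(stats)
    E = vulnerability()
    weights = stats["area"] / stats["A_n"][:, None]
    R = indices["I"] * E[None, :]
    return np.nansum(weights * R, axis=1)


def compute_risk_grid(landuse: Raster, cell_km: float = 20.0,
                      grid: RiskGrid | None = None) -> RiskGrid:
    """Build (or reuse) the plot grid and attach per-plot indices and ERI."""
    if grid is None:
        grid = make_grid(landuse, cell_km=cell_km)
    stats = patch_statistics(landuse, grid)
    idx = landscape_indices(stats)
    table = grid.table.copy()
    for j, cls in enumerate(CLASS_CODES):
        name = CLASS_NAMES[cls]
        table[f"C_{name}"] = idx["C"][:, j]
        table[f"I_{name}"] = idx["I"][:, j]
    table["eri"] = eri(stats, idx)
    return RiskGrid(table, grid.plot_size_cells, grid.template,
                    grid.n_grid_rows, grid.n_grid_cols)


# ---------------------------------------------------------------------------
# variogram + ordinary kriging

def _spherical(h: np.ndarray, nugget: float, psill: float,
               rng: float) -> np.ndarray:
    hn = np.minimum(h / max(rng, 1e-12), 1.0)
    gamma = nugget + psill * (1.5 * hn - 0.5 * hn ** 3)
    return np.where(h > 0, gamma, 0.0)


def fit_spherical_variogram(coords: np.ndarray, values: np.ndarray,
                            n_bins: int = 12) -> tuple[float, float, float]:
    """WLS fit of a spherical semivariogram (nugget, partial sill, range).

    The empirical semivariogram uses ``n_bins`` equal-width lag bins up to
    half the maximum pairwise distance; bins are weighted by pair count
    over squared model value (Cressie weights).
    """
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    g = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    hmax = h.max() / 2.0
    edges = np.linspace(0, hmax, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (h > lo) & (h <= hi)
        if sel.sum() >= 1:
            centers.append(h[sel].mean())
            gammas.append(g[sel].mean())
            counts.append(sel.sum())
    centers = np.asarray(centers)
    gammas = np.asarray(gammas)
    counts = np.asarray(counts, dtype=float)
    var = values.var()
    if var < 1e-30 or len(centers) < 3:
        return 0.0, max(var, 1e-30), hmax or 1.0

    def resid(p):
        model = _spherical(centers, *p)
        return np.sqrt(counts) * (gammas - model) / np.maximum(model, 1e-12)

    p0 = np.array([1e-6 * var, var, hmax])
    sol = least_squares(resid, p0, bounds=([0, 1e-12 * var, 1e-6],
                                           [var * 10, var * 100, hmax * 4]))
    return tuple(sol.x)


def _ok_weights_solve(coords: np.ndarray, params, targets: np.ndarray,
                      values: np.ndarray) -> np.ndarray:
    from scipy.linalg import lu_factor, lu_solve
    n = len(coords)
    gamma_dd = _spherical(cdist(coords, coords), *params)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma_dd
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    lu = lu_factor(A)
    gamma_dt = _spherical(cdist(coords, targets), *params)
    rhs = np.vstack([gamma_dt, np.ones((1, len(targets)))])
    lam = lu_solve(lu, rhs)
    return lam[:n].T @ values


def idw(coords: np.ndarray, values: np.ndarray, targets: np.ndarray,
        power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation (exact at data points)."""
    d = cdist(targets, coords)
    out = np.empty(len(targets))
    at_point = d < 1e-9
    hit = at_point.any(axis=1)
    out[hit] = values[np.argmax(at_point[hit], axis=1)]
    w = 1.0 / np.maximum(d[~hit], 1e-300) ** power
    out[~hit] = (w @ values) / w.sum(axis=1)
    return out


def interpolate_surface(grid: RiskGrid, column: str = "eri",
                        method: str = "ordinary_kriging",
                        classify: bool = False) -> RiskSurface:
    """Interpolate per-plot values at plot centroids onto the template grid.

    Ordinary kriging with a WLS-fitted spherical variogram by default;
    inverse-distance weighting as an explicit method or automatic fallback
    when the kriging system is singular.
    """
    if len(grid) < 10 and method == "ordinary_kriging":
        warnings.warn("fewer than 10 plots; kriging variogram poorly "
                      "constrained", RuntimeWarning, stacklevel=2)
    coords = grid.table[["centroid_x", "centroid_y"]].to_numpy(float)
    values = grid.table[column].to_numpy(float)
    template = grid.template
    xs, ys = template.cell_centers()
    targets = np.column_stack([xs.ravel(), ys.ravel()])

    if len(values) == 0 or np.ptp(values) < 1e-30:
        est = np.full(len(targets), values[0] if len(values) else np.nan)
        method_used = "constant"
    elif method == "idw":
        est = idw(coords, values, targets)
        method_used = "idw"
    else:
        params = fit_spherical_variogram(coords, values)
        try:
            est = _ok_weights_solve(coords, params, targets, values)
            method_used = "ordinary_kriging"
        except np.linalg.LinAlgError:
            warnings.warn("singular kriging system; falling back to IDW",
                          RuntimeWarning, stacklevel=2)
            est = idw(coords, values, targets)
            method_used = "idw"
    surf = template.like(est.reshape(template.shape).astype(float),
                         nodata=np.nan)
    surface = RiskSurface(eri=surf, method=method_used)
    if classify:
        return classify_risk(surface)
    return surface


def jenks_breaks(values, k: int = 5) -> list[float]:
    """Jenks natural breaks: k-class partition minimising within-class SSD.

    Returns the k-1 interior break values (upper bounds of the first k-1
    classes, taken at class-max elements of the optimal partition).
    Exact dynamic program, O(k n^2).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if len(np.unique(x)) < k:
        raise ValueError("fewer distinct values than classes")
    # prefix sums for O(1) segment SSD
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def ssd(i, j):     # segment x[i:j] (0-based, j exclusive), vectorized in i
        cnt = j - i
        s = cs[j] - cs[i]
        s2 = cs2[j] - cs2[i]
        return s2 - s * s / cnt

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            i = np.arange(kk - 1, j)
            cand = cost[kk - 1, i] + ssd(i, j)
            best = int(np.argmin(cand))
            cost[kk, j] = cand[best]
            cut[kk, j] = i[best]
    # recover break positions
    bounds = []
    j = n
    for kk in range(k, 0, -1):
        i = cut[kk, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]          # interior cut indices
    return [float(x[b - 1]) for b in bounds]


def classify_risk(surface: RiskSurface,
                  breaks: str | tuple = "paper_defaults",
                  seed: int = 0, max_sample: int = 3000) -> RiskSurface:
    """Bin the ERI surface into five bands (codes 1=low .. 5=high).

    ``breaks`` is either the fixed reporting thresholds
    (``"paper_defaults"``), ``"jenks"`` for 5-class natural breaks (fitted
    on a seeded subsample when the surface is large), or an explicit
    4-tuple of thresholds.
    """
    vals = surface.eri.values
    finite = np.isfinite(vals)
    if breaks == "paper_defaults":
        thresholds = PAPER_RISK_BREAKS
    elif breaks == "jenks":
        data = vals[finite]
        if data.size > max_sample:
            rng = np.random.default_rng(seed)
            data = rng.choice(data, size=max_sample, replace=False)
        thresholds = tuple(jenks_breaks(data, 5))
    else:
        thresholds = tuple(breaks)
        if len(thresholds) != 4:
            raise ValueError("need exactly 4 thresholds for 5 bands")
    bands = np.where(finite,
                     np.digitize(vals, thresholds, right=True) + 1, 0)
    band_raster = surface.eri.like(bands.astype(np.int8), nodata=0)
    return RiskSurface(eri=surface.eri, bands=band_raster,
                       breaks=thresholds, method=surface.method)
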