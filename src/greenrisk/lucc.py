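"""Markov transition estimation and constrained cellular-automaton projection.

The land-use change model has two parts.  A Markov chain estimated from two
observed epochs supplies the *demand* side: how many cells each class should
occupy after a given number of model periods.  A cellular automaton supplies
the *allocation* side: which cells change, scored by multi-criteria
suitability times neighbourhood density, subject to per-class conversion
constraints encoding the policy scenario (natural projection, NP, versus
black-land conservation and utilisation, BCU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import (CLASS_CODES, CLASS_NAMES, CONSTRUCTION, CULTIVATED,
                     FOREST, GRASSLAND, N_CLASSES, Raster)
from .synthetic import DRIVER_NAMES, DriverStack

__all__ = [
    "TransitionModel", "ScenarioRules", "SuitabilityAtlas",
    "estimate_transition", "project_class_areas", "build_suitability",
    "apply_scenario_constraints", "simulate_ca", "kappa",
    "DEFAULT_ORIENTATIONS",
]


@dataclass
class TransitionModel:
    """Observed class-transition structure between two epochs.

    ``area_matrix[i, j]`` counts cells that were class ``i+1`` at the first
    epoch and class ``j+1`` at the second; ``prob_matrix`` is its row
    normalisation, with identity rows substituted for classes absent at the
    first epoch.
    """

    prob_matrix: np.ndarray
    area_matrix: np.ndarray
    period_years: int = 10

    def __post_init__(self) -> None:
        self.prob_matrix = np.asarray(self.prob_matrix, dtype=float)
        self.area_matrix = np.asarray(self.area_matrix)
        if self.prob_matrix.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("prob_matrix must be 6x6")
        rows = self.prob_matrix.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-9:
            raise ValueError("prob_matrix rows must sum to 1")


@dataclass
class ScenarioRules:
    """Policy scenario switches for the conversion-constraint builder."""

    scenario_id: str = "NP"              # "NP" or "BCU"
    slope_threshold_deg: float = 15.0
    protect_green_from_construction: bool = True    # BCU rule (i), first half
    freeze_cultivated: bool = True                  # BCU rule (i), second half
    no_steep_reclamation: bool = True               # BCU rule (ii)
    steep_cultivated_to_forest_grass: bool = True   # BCU rule (iii)
    protect_blacksoil: bool = True                  # BCU rule (iv)

    def __post_init__(self) -> None:
        sid = self.scenario_id.upper()
        if sid not in ("NP", "BCU"):
            raise ValueError(f"unknown scenario {self.scenario_id!r}")
        self.scenario_id = sid
        if self.slope_threshold_deg <= 0:
            raise ValueError("slope_threshold_deg must be positive")


@dataclass
class SuitabilityAtlas:
    """Per-class suitability surfaces in [0, 1] and conversion masks.

    ``constraints[j]`` is boolean per cell: False forbids *conversion* of
    that cell to class code ``j`` (cells always may keep their class).
    """

    suitability: dict
    constraints: dict

    def __post_init__(self) -> None:
        for cls, r in self.suitability.items():
            v = r.values
            if not np.isfinite(v).all() or v.min() < 0 or v.max() > 1:
                raise ValueError(f"suitability for class {cls} not in [0,1]")


def estimate_transition(map_t0: Raster, map_t1: Raster,
                        period_years: int = 10) -> TransitionModel:
    """Count observed transitions and row-normalise into probabilities."""
    map_t0.check_aligned(map_t1)
    valid = map_t0.valid_mask() & map_t1.valid_mask()
    if not valid.any():
        raise ValueError("no valid overlapping cells")
    a = map_t0.values[valid].astype(int) - 1
    b = map_t1.values[valid].astype(int) - 1
    area = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(area, (a, b), 1)
    rows = area.sum(axis=1, keepdims=True)
    prob = np.where(rows > 0, area / np.maximum(rows, 1), 0.0)
    empty = rows[:, 0] == 0
    prob[empty] = np.eye(N_CLASSES)[empty]   # absent classes persist
    return TransitionModel(prob, area, period_years)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative fractional counts to integers summing to total."""
    floors = np.floor(fractions).astype(np.int64)
    short = total - int(floors.sum())
    if short > 0:
        order = np.argsort(-(fractions - floors), kind="stable")
        floors[order[:short]] += 1
    elif short < 0:     # can occur only through float round-up at the edge
        order = np.argsort(fractions - floors, kind="stable")
        for idx in order:
            if short == 0:
                break
            if floors[idx] > 0:
                floors[idx] -= 1
                short += 1
    return floors


def project_class_areas(model: TransitionModel, map_t0: Raster,
                        steps: int = 1) -> np.ndarray:
    """Markov demand: expected class cell counts after ``steps`` periods."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    counts = map_t0.class_counts().astype(float)
    target = counts @ np.linalg.matrix_power(model.prob_matrix, steps)
    return _largest_remainder(target, int(counts.sum()))


# orientation: +1 means the driver raises suitability for the class,
# -1 lowers it.  Chosen to reflect the usual accessibility/terrain logic:
# flat, warm, wet land suits agriculture; construction follows people,
# economy and roads; forest and grassland tolerate steeper, remoter land.
DEFAULT_ORIENTATIONS: dict[int, dict[str, int]] = {
    CULTIVATED: {"elevation": -1, "slope": -1, "temperature": +1,
                 "precipitation": +1, "population": +1, "gdp": +1,
                 "dist_national": -1, "dist_provincial": -1,
                 "dist_highway": -1},
    FOREST: {"elevation": +1, "slope": +1, "temperature": -1,
             "precipitation": +1, "population": -1, "gdp": -1,
             "dist_national": +1, "dist_provincial": +1, "dist_highway": +1},
    GRASSLAND: {"elevation": +1, "slope": +1, "temperature": -1,
                "precipitation": -1, "population": -1, "gdp": -1,
                "dist_national": +1, "dist_provincial": +1,
                "dist_highway": +1},
    4: {"elevation": -1, "slope": -1, "temperature": +1, "precipitation": +1,
        "population": -1, "gdp": -1, "dist_national": +1,
        "dist_provincial": +1, "dist_highway": +1},
    CONSTRUCTION: {"elevation": -1, "slope": -1, "temperature": +1,
                   "precipitation": -1, "population": +1, "gdp": +1,
                   "dist_national": -1, "dist_provincial": -1,
                   "dist_highway": -1},
    6: {"elevation": +1, "slope": +1, "temperature": -1, "precipitation": -1,
        "population": -1, "gdp": -1, "dist_national": +1,
        "dist_provincial": +1, "dist_highway": +1},
}


def _rescale(values: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi - lo < 1e-300:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def build_suitability(drivers: DriverStack, rules: ScenarioRules,
                      weights: dict | None = None,
                      orientations: dict | None = None,
                      constraints: dict | None = None) -> SuitabilityAtlas:
    """Multi-criteria suitability: weighted linear combination of rescaled
    drivers, oriented per class, multiplied by the conversion masks.

    ``weights`` maps class code -> {driver name: weight}, each class's
    weights summing to 1; the default weighs all nine drivers equally.
    """
    orientations = orientations or DEFAULT_ORIENTATIONS
    if weights is None:
        weights = {c: {d: 1.0 / len(DRIVER_NAMES) for d in DRIVER_NAMES}
                   for c in CLASS_CODES}
    suit = {}
    for cls in CLASS_CODES:
        w = weights[cls]
        total = sum(w.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weights for class {cls} sum to {total}, not 1")
        acc = None
        for name, weight in w.items():
            if name not in drivers:
                raise KeyError(f"missing driver {name!r}")
            scaled = _rescale(drivers[name].values.astype(float))
            if orientations.get(cls, {}).get(name, +1) < 0:
                scaled = 1.0 - scaled
            acc = weight * scaled if acc is None else acc + weight * scaled
        if constraints is not None:
            acc = acc * constraints[cls]
        template = drivers[next(iter(w))]
        suit[cls] = template.like(np.clip(acc, 0.0, 1.0), nodata=np.nan)
    if constraints is None:
        shape = next(iter(suit.values())).shape
        constraints = {c: np.ones(shape, dtype=bool) for c in CLASS_CODES}
    return SuitabilityAtlas(suitability=suit, constraints=constraints)


def apply_scenario_constraints(rules: ScenarioRules, drivers: DriverStack,
                               map_t0: Raster) -> dict:
    """Per-class boolean conversion masks implementing the scenario rules.

    NP allows every conversion.  BCU applies the black-land regulation:
    (i) land now under green cover (classes 1-4) may not convert to
    construction, and cultivated land is frozen except that steeply sloping
    cultivated cells may move to forest or grassland; (ii) no steep cell may
    be newly cultivated; (iii) steep cultivated cells may convert only to
    forest or grassland; (iv) nothing converts to construction on the
    black-soil mask.  "Steep" means slope above ``slope_threshold_deg``.
    """
    shape = map_t0.shape
    masks = {c: np.ones(shape, dtype=bool) for c in CLASS_CODES}
    if rules.scenario_id == "NP":
        return masks
    if "slope" not in drivers:
        raise ValueError("BCU scenario requires a slope driver")
    if drivers.blacksoil is None:
        raise ValueError("BCU scenario requires a black-soil mask")
    slope = drivers["slope"].values
    steep = slope > rules.slope_threshold_deg
    lu = map_t0.values
    green_now = np.isin(lu, (1, 2, 3, 4))
    cultivated_now = lu == CULTIVATED

    if rules.protect_green_from_construction:
        masks[CONSTRUCTION] &= ~green_now
    if rules.freeze_cultivated:
        # cultivated land may leave only towards forest/grassland on steep
        # slopes; every other outbound conversion is forbidden
        for cls in CLASS_CODES:
            if cls == CULTIVATED:
                continue
            if cls in (FOREST, GRASSLAND):
                if rules.steep_cultivated_to_forest_grass:
                    masks[cls] &= ~cultivated_now | steep
                else:
                    masks[cls] &= ~cultivated_now
            else:
                masks[cls] &= ~cultivated_now
    if rules.no_steep_reclamation:
        masks[CULTIVATED] &= ~steep
    if rules.protect_blacksoil:
        masks[CONSTRUCTION] &= drivers.blacksoil.values != 1
    return masks


def _neighborhood_density(onehot: np.ndarray, size: int) -> np.ndarray:
    """Fraction of the size x size window occupied by the class."""
    return ndimage.uniform_filter(onehot.astype(float), size=size,
                                  mode="constant", cval=0.0)


def simulate_ca(map_t0: Raster, targets: np.ndarray, atlas: SuitabilityAtlas,
                filter_size: int = 5, iterations: int = 10,
                seed: int = 0, log: list | None = None) -> Raster:
    """Allocate Markov demand on the map with a contiguity-seeking CA.

    Each of ``iterations`` passes allocates an equal share of every class's
    net demand.  Candidate cells are scored by suitability times the
    fraction of the ``filter_size`` x ``filter_size`` neighbourhood already
    occupied by the class; permitted candidates convert in descending score
    order, drawing only from classes that still hold surplus cells.  Ties
    are broken by a seeded random jitter so runs are reproducible.
    """
    targets = np.asarray(targets, dtype=np.int64)
    valid = map_t0.valid_mask()
    n_valid = int(valid.sum())
    if int(targets.sum()) != n_valid:
        raise ValueError("targets must sum to the valid-cell count")
    rng = np.random.default_rng(seed)
    state = np.array(map_t0.values, dtype=np.int16, copy=True)
    tol = max(1, int(0.01 * n_valid))

    for it in range(iterations):
        counts = np.bincount(state[valid], minlength=N_CLASSES + 1)[1:]
        deficit = targets - counts          # >0: class must grow
        if np.abs(deficit).max() == 0:
            break
        remaining_iters = iterations - it
        for j_idx in np.argsort(-deficit, kind="stable"):
            need = int(deficit[j_idx])
            if need <= 0:
                continue
            quota = int(np.ceil(need / remaining_iters))
            cls = CLASS_CODES[j_idx]
            counts_now = np.bincount(state[valid],
                                     minlength=N_CLASSES + 1)[1:]
            surplus = counts_now - targets   # donors have surplus > 0
            donor_classes = [CLASS_CODES[i] for i in range(N_CLASSES)
                             if surplus[i] > 0]
            if not donor_classes:
                break
            density = _neighborhood_density(state == cls, filter_size)
            score = atlas.suitability[cls].values * (density + 1e-6)
            cand = (valid & atlas.constraints[cls]
                    & np.isin(state, donor_classes) & (state != cls))
            idx = np.flatnonzero(cand)
            if idx.size == 0:
                continue
            s = score.flat[idx] + rng.uniform(0, 1e-12, size=idx.size)
            order = idx[np.argsort(-s, kind="stable")]
            budget = {c: int(surplus[c - 1]) for c in donor_classes}
            converted = 0
            for cell in order:
                if converted >= quota:
                    break
                src = int(state.flat[cell])
                if budget.get(src, 0) > 0:
                    state.flat[cell] = cls
                    budget[src] -= 1
                    converted += 1
            if log is not None:
                log.append({"iteration": it, "class": CLASS_NAMES[cls],
                            "quota": quota, "converted": converted})

    final = np.bincount(state[valid], minlength=N_CLASSES + 1)[1:]
    gap = int(np.abs(final - targets).max())
    if gap > tol:
        warnings.warn(
            f"CA allocation shortfall: max class-count gap {gap} cells "
            f"exceeds 1% of valid area (constraints may be binding)",
            RuntimeWarning, stacklevel=2)
    return map_t0.like(state)


def kappa(sim: Raster, ref: Raster) -> float:
    """Cohen's kappa agreement between two categorical maps."""
    sim.check_aligned(ref)
    valid = sim.valid_mask() & ref.valid_mask()
    if not valid.any():
        raise ValueError("no valid overlapping cells")
    a = sim.values[valid].astype(int)
    b = ref.values[valid].astype(int)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for cls in np.union1d(a, b):
        p_e += (np.mean(a == cls)) * (np.mean(b == cls))
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
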