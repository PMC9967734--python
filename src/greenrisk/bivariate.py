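"""Quantitative and spatial association between two per-unit variables.

Used to relate per-plot carbon-storage change to landscape-risk change:
a Kolmogorov-Smirnov normality gate decides between Pearson and Spearman
reporting; bivariate global and local Moran statistics with queen
contiguity weights measure spatial association; a conditional permutation
test labels units into the five LISA categories (H-H, L-L, L-H, H-L,
N-S).

The global statistic is computed as

    I = n * sum_ij W_ij Qk_i Ql_j / ((n - 1) * sum_ij W_ij)

with Q the z-scores (population SD) of the two attributes.  A
``geoda_style`` toggle computes the conventional row-standardized
cross-Moran ``mean_i(Qk_i * lag_i(Ql))`` for cross-checking against other
software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "WeightsMatrix", "LISAMap", "ks_normality", "spearman", "build_weights",
    "zscore", "global_bivariate_moran", "local_bivariate_moran",
    "lisa_classify", "LISA_LABELS",
]

LISA_LABELS = ("H-H", "L-L", "L-H", "H-L", "N-S")


@dataclass
class WeightsMatrix:
    """Sparse spatial weights over n units."""

    w: sparse.csr_matrix
    scheme: str = "queen"
    row_standardized: bool = True
    islands: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def lag(self, x: np.ndarray) -> np.ndarray:
        return self.w @ x


@dataclass
class LISAMap:
    local_i: np.ndarray
    p_value: np.ndarray
    labels: np.ndarray        # strings from LISA_LABELS
    alpha: float

    def label_fractions(self) -> pd.Series:
        n = len(self.labels)
        return pd.Series({lab: float((self.labels == lab).sum()) / n
                          for lab in LISA_LABELS}, name="fraction")


def ks_normality(sample, n_mc: int = 10_000, seed: int = 0
                 ) -> tuple[float, float]:
    """One-sample K-S test against a normal with estimated mean/SD.

    Because the null parameters are estimated from the same sample, the
    textbook K-S p-value is biased; the p returned here is the Lilliefors
    Monte-Carlo p (seeded, ``n_mc`` replicates).
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 observations")
    sd = x.std(ddof=1)
    if sd < 1e-300:
        raise ValueError("zero-variance sample")
    d_obs = stats.kstest(x, "norm", args=(x.mean(), sd)).statistic

    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, n))
    sims.sort(axis=1)
    means = sims.mean(axis=1, keepdims=True)
    sds = sims.std(axis=1, ddof=1, keepdims=True)
    cdf = stats.norm.cdf((sims - means) / sds)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    d_sim = np.maximum(d_plus, d_minus)
    p = (np.count_nonzero(d_sim >= d_obs) + 1) / (n_mc + 1)
    return float(d_obs), float(p)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    rx = stats.rankdata(x)    # average ranks for ties
    ry = stats.rankdata(y)
    if rx.std() < 1e-300 or ry.std() < 1e-300:
        raise ValueError("constant vector has no rank correlation")
    return float(np.corrcoef(rx, ry)[0, 1])


def build_weights(grid, scheme: str = "queen",
                  standardize: str = "row") -> WeightsMatrix:
    """Contiguity weights between the sampling plots of a RiskGrid.

    Queen contiguity joins plots sharing an edge or a corner (8 interior
    neighbours); rook joins edge-sharing plots only.  Plots without any
    neighbour (islands) are flagged with a warning and keep zero rows.
    """
    tab = grid.table
    n = len(tab)
    pos = {(int(r), int(c)): i for i, (r, c) in
           enumerate(zip(tab["block_row"], tab["block_col"]))}
    if scheme == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    elif scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rows, cols = [], []
    for (r, c), i in pos.items():
        for dr, dc in offsets:
            j = pos.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    w = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    degree = np.asarray(w.sum(axis=1)).ravel()
    islands = np.flatnonzero(degree == 0)
    if islands.size:
        warnings.warn(f"{islands.size} island unit(s) with no neighbours",
                      RuntimeWarning, stacklevel=2)
    if standardize == "row":
        inv = np.where(degree > 0, 1.0 / np.maximum(degree, 1), 0.0)
        w = sparse.diags(inv) @ w
    return WeightsMatrix(w=w.tocsr(), scheme=scheme,
                         row_standardized=(standardize == "row"),
                         islands=islands)


def lattice_weights(n_rows: int, n_cols: int, scheme: str = "queen",
                    standardize: str = "row") -> WeightsMatrix:
    """Contiguity weights for a full regular lattice of units."""
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    tab = pd.DataFrame({"block_row": rr.ravel(), "block_col": cc.ravel()})

    class _Lattice:
        table = tab

    return build_weights(_Lattice, scheme=scheme, standardize=standardize)


def zscore(x: np.ndarray) -> np.ndarray:
    """z-standardization with the population (ddof=0) SD."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd < 1e-300:
        raise ValueError("zero-variance attribute")
    return (x - x.mean()) / sd


def global_bivariate_moran(x_k, x_l, W: WeightsMatrix,
                           geoda_style: bool = False) -> float:
    """Bivariate global Moran's I between attributes k and l.

    Default: ``n * sum W_ij Qk_i Ql_j / ((n-1) * sum W_ij)``.  With
    ``geoda_style=True``: ``mean(Qk * lag(Ql))`` (row-standardized
    cross-Moran, for comparison with desktop spatial software).
    """
    qk, ql = zscore(x_k), zscore(x_l)
    n = len(qk)
    if n < 2:
        raise ValueError("need at least 2 units")
    cross = float(qk @ (W.w @ ql))
    s0 = float(W.w.sum())
    if geoda_style:
        return cross / n
    return n * cross / ((n - 1) * s0)


def local_bivariate_moran(x_k, x_l, W: WeightsMatrix) -> np.ndarray:
    """Per-unit local bivariate Moran: I_i = Qk_i * sum_j W_ij Ql_j."""
    qk, ql = zscore(x_k), zscore(x_l)
    return qk * (W.w @ ql)


def lisa_classify(x_k, x_l, W: WeightsMatrix, alpha: float = 0.05,
                  n_perm: int = 999, seed: int = 0) -> LISAMap:
    """Five-category LISA labels with a conditional permutation test.

    For each unit the focal value Qk_i is held fixed while the other
    units' Ql values are randomly reassigned to its neighbours (``n_perm``
    seeded draws without replacement); the pseudo p-value is
    ``(#{|I_perm| >= |I_obs|} + 1) / (n_perm + 1)``.  Significant units
    are labelled by the quadrant of (Qk_i, spatial lag of Ql); all others
    are N-S.
    """
    x_l = np.asarray(x_l, dtype=float)
    if np.ptp(x_l) < 1e-300:
        warnings.warn("constant second attribute: all units N-S",
                      RuntimeWarning, stacklevel=2)
        n = len(x_l)
        return LISAMap(np.zeros(n), np.ones(n),
                       np.array(["N-S"] * n), alpha)
    qk, ql = zscore(x_k), zscore(x_l)
    n = len(qk)
    lag = W.w @ ql
    i_obs = qk * lag
    w_dense = W.w  # csr

    rng = np.random.default_rng(seed)
    degrees = np.diff(w_dense.indptr)
    max_k = int(degrees.max()) if n else 0
    # one pool of seeded partial permutations of the n-1 "other" slots,
    # shared across units (standard conditional-randomization shortcut)
    perm_pool = np.empty((n_perm, max_k), dtype=np.int64)
    for r in range(n_perm):
        perm_pool[r] = rng.permutation(n - 1)[:max_k]

    p = np.ones(n)
    for i in range(n):
        k_i = degrees[i]
        if k_i == 0:
            continue
        others = np.delete(np.arange(n), i)
        row = w_dense.getrow(i)
        wvals = row.data          # weights of the k_i neighbours
        draws = ql[others[perm_pool[:, :k_i]]]
        lag_perm = draws @ wvals
        i_perm = qk[i] * lag_perm
        p[i] = (np.count_nonzero(np.abs(i_perm) >= abs(i_obs[i])) + 1) \
            / (n_perm + 1)

    labels = np.full(n, "N-S", dtype=object)
    sig = p <= alpha
    hi_k, hi_lag = qk > 0, lag > 0
    labels[sig & hi_k & hi_lag] = "H-H"
    labels[sig & ~hi_k & ~hi_lag] = "L-L"
    labels[sig & ~hi_k & hi_lag] = "L-H"
    labels[sig & hi_k & ~hi_lag] = "H-L"
    return LISAMap(local_i=i_obs, p_value=p, labels=labels.astype(str),
                   alpha=alpha)
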