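"""Coupling coordination between carbon storage and landscape risk.

Two subsystem indicators (here: normalized green-space carbon W and
normalized landscape ecological risk S) are combined into

* a coupling degree       ``C = 2 * sqrt(W S / (W + S)^2)``
* a development index     ``T = alpha W + beta S``
* a coordination degree   ``D = sqrt(C T)``

C measures how balanced the two subsystems are (1 iff W = S), T their
joint level, and D the geometric compromise of the two.  Inputs are
min-max normalized across the pooled set of units being compared, so D
values are only comparable within the stated pool.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CouplingScore", "minmax_normalize", "coupling", "development",
           "coordination", "couple", "couple_table", "round_half_up"]


@dataclass
class CouplingScore:
    W: float
    S: float
    C: float
    T: float
    D: float
    alpha: float = 0.5
    beta: float = 0.5


def round_half_up(x: float, digits: int = 3) -> float:
    """Decimal round-half-up, the convention used for reported scores."""
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def minmax_normalize(values, inverse: bool = False) -> np.ndarray:
    """Polar-difference (min-max) standardization onto [0, 1].

    ``inverse=True`` flips the orientation ((max - x)/(max - min)), for
    indicators where a high raw value means a low benefit.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi - lo < 1e-300:
        raise ValueError("cannot normalize a constant vector")
    z = (x - lo) / (hi - lo)
    return 1.0 - z if inverse else z


def coupling(W: float, S: float) -> float:
    """Coupling degree C = 2 sqrt(W S / (W + S)^2); 1 iff W = S."""
    W, S = float(W), float(S)
    if W < 0 or S < 0:
        raise ValueError("W and S must be non-negative")
    if W + S == 0:
        warnings.warn("coupling undefined at W = S = 0; returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return 2.0 * np.sqrt(W * S / (W + S) ** 2)


def development(W: float, S: float, alpha: float = 0.5,
                beta: float = 0.5) -> float:
    """Development index T = alpha W + beta S (alpha + beta = 1)."""
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("alpha, beta must be non-negative and sum to 1")
    return alpha * float(W) + beta * float(S)


def coordination(C: float, T: float) -> float:
    """Coupling coordination degree D = sqrt(C T)."""
    return float(np.sqrt(float(C) * float(T)))


def couple(W: float, S: float, alpha: float = 0.5,
           beta: float = 0.5) -> CouplingScore:
    """Full (W, S, C, T, D) score for one analysis unit."""
    C = coupling(W, S)
    T = development(W, S, alpha, beta)
    return CouplingScore(W=W, S=S, C=C, T=T, D=coordination(C, T),
                         alpha=alpha, beta=beta)


def couple_table(units: pd.DataFrame, w_col: str = "W_raw",
                 s_col: str = "S_raw", alpha: float = 0.5, beta: float = 0.5,
                 normalize: bool = True, inverse_s: bool = False,
                 digits: int | None = None) -> pd.DataFrame:
    """Score a pool of units; normalization is over the pooled columns.

    Returns the input with W, S, C, T, D columns appended; ``digits``
    optionally rounds the five scores half-up for reporting.
    """
    out = units.copy()
    if normalize:
        out["W"] = minmax_normalize(out[w_col])
        out["S"] = minmax_normalize(out[s_col], inverse=inverse_s)
    else:
        out["W"], out["S"] = out[w_col], out[s_col]
    scores = [couple(w, s, alpha, beta)
              for w, s in zip(out["W"], out["S"])]
    out["C"] = [sc.C for sc in scores]
    out["T"] = [sc.T for sc in scores]
    out["D"] = [sc.D for sc in scores]
    if digits is not None:
        for col in ("W", "S", "C", "T", "D"):
            out[col] = [round_half_up(v, digits) for v in out[col]]
    return out
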