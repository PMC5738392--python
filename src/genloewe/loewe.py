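"""Generalized Loewe (concentration-additivity) null surface.

Classical Loewe additivity models an assay as a single-step enzymatic
reaction in which all compounds compete for one binding site.  The
occupancy ``o`` of a dose combination (c_1, ..., c_n) then solves the
isobole equation

    sum_j (c_j / i_j) * (1/o - 1)^(1/h_j) = 1,

whose left side is continuous and strictly decreasing in ``o`` on (0, 1)
(from +inf to 0), so the root exists and is unique whenever any dose is
positive.  Classical Loewe maps occupancy to readout with a single shared
maximum; the generalization implemented here keeps the occupancy equation
untouched but lets each compound carry its own scaling (m_j - b), giving
the combination readout as the occupancy-weighted blend

    r = b + o * sum_j (m_j - b) * f_j,     f_j = (c_j / i_j) * (1/o - 1)^(1/h_j),

where f_j is the fraction of bound enzyme bound specifically by compound j
(the f_j sum to 1 by the occupancy equation).  This accommodates partial,
neutral and inverse agonists: a neutral antagonist (m_j == b) still competes
for occupancy but contributes nothing to the readout sum, and the model
reduces exactly to classical Loewe when all m_j coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .marginals import MarginalCurve

__all__ = [
    "NullPrediction",
    "NullSurface",
    "solve_occupancy",
    "predict_readout",
    "predict_surface",
]

_EPS_O = 1e-12
_BISECT_ITER = 100


def _curve_arrays(curves: Sequence[MarginalCurve]):
    if len(curves) < 1:
        raise ValueError("need at least one marginal curve")
    ec50 = np.array([c.ec50 for c in curves])
    inv_h = np.array([1.0 / c.hill for c in curves])
    return ec50, inv_h


def _check_shared_baseline(curves: Sequence[MarginalCurve]) -> float:
    b0 = curves[0].b
    tol = 1e-6 * max(1.0, abs(b0))
    if any(abs(c.b - b0) > tol for c in curves):
        raise ValueError("all curves must share the same baseline readout")
    return b0


def _occupancy_grid(curves: Sequence[MarginalCurve], C: np.ndarray) -> np.ndarray:
    """Solve the occupancy equation for every row of the (k, n) dose matrix."""
    ec50, inv_h = _curve_arrays(curves)
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] != len(curves):
        raise ValueError("dose matrix must be (n_points, n_compounds)")
    if np.any(C < 0) or not np.isfinite(C).all():
        raise ValueError("doses must be finite and non-negative")

    o = np.zeros(C.shape[0])
    active = (C > 0).any(axis=1)
    if not active.any():
        return o
    W = C[active] / ec50  # dose fractions c_j / i_j

    lo = np.full(W.shape[0], _EPS_O)
    hi = np.full(W.shape[0], 1.0 - _EPS_O)
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        base = (1.0 - mid) / mid
        g = (W * base[:, None] ** inv_h[None, :]).sum(axis=1)
        too_small = g > 1.0  # LHS decreasing: root lies at larger o
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    o[active] = 0.5 * (lo + hi)
    return o


def solve_occupancy(curves: Sequence[MarginalCurve], doses) -> float:
    """Occupancy of a single dose combination under concentration additivity.

    Returns the unique root in (0, 1) of the Loewe isobole equation by
    bracketed bisection; returns 0 for the untreated point (all doses zero).
    Compounds dosed at zero drop out of the sum.
    """
    C = np.asarray(doses, dtype=float)[None, :]
    return float(_occupancy_grid(curves, C)[0])


@dataclass(frozen=True)
class NullPrediction:
    """Null-model state at one dose combination.

    ``weights`` are the fractions f_j of bound enzyme bound by each
    compound; they sum to 1 over compounds with positive dose (all zero at
    the untreated point).
    """

    occupancy: float
    weights: np.ndarray
    readout: float


def _weights_and_readout(curves, C, o):
    ec50, inv_h = _curve_arrays(curves)
    b = _check_shared_baseline(curves)
    m = np.array([c.m for c in curves])
    W = np.zeros_like(C, dtype=float)
    pos = o > 0
    if pos.any():
        base = (1.0 - o[pos]) / o[pos]
        W[pos] = (C[pos] / ec50) * base[:, None] ** inv_h[None, :]
        W[pos] *= (C[pos] > 0)
    r = b + o * (W * (m - b)[None, :]).sum(axis=1)
    return W, r


def predict_readout(curves: Sequence[MarginalCurve], doses) -> NullPrediction:
    """Predicted combination readout under the generalized Loewe null.

    Solves for the occupancy, forms the per-compound bound fractions f_j and
    blends the compound-specific scalings (m_j - b).  With equal maxima this
    reduces algebraically to the classical Loewe readout b + o*(m - b).
    """
    C = np.asarray(doses, dtype=float)[None, :]
    o = _occupancy_grid(curves, C)
    W, r = _weights_and_readout(curves, C, o)
    return NullPrediction(occupancy=float(o[0]), weights=W[0], readout=float(r[0]))


@dataclass(frozen=True)
class NullSurface:
    """Null predictions over a grid of dose combinations, in grid order."""

    doses: np.ndarray       # (k, n_compounds)
    occupancy: np.ndarray   # (k,)
    weights: np.ndarray     # (k, n_compounds)
    predicted: np.ndarray   # (k,)

    def __len__(self) -> int:
        return len(self.predicted)

    def to_frame(self) -> pd.DataFrame:
        if self.doses.shape[1] != 2:
            raise ValueError("long-format frame is defined for 2-compound surfaces")
        return pd.DataFrame(
            {
                "d1": self.doses[:, 0],
                "d2": self.doses[:, 1],
                "occupancy": self.occupancy,
                "predicted": self.predicted,
            }
        )


def predict_surface(curves: Sequence[MarginalCurve], grid) -> NullSurface:
    """Vectorized :func:`predict_readout` over a grid of dose combinations."""
    C = np.asarray(grid, dtype=float)
    if C.size == 0:
        C = C.reshape(0, len(curves))
    o = _occupancy_grid(curves, C)
    W, r = _weights_and_readout(curves, C, o)
    return NullSurface(doses=C, occupancy=o, weights=W, predicted=r)
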