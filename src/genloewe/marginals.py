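"""Shared-baseline Hill (four-parameter log-logistic) mono-therapy models.

The concentration-response of a single compound in a combination experiment
is described by the Hill occupancy

    o_j(c) = 1 / (1 + (i_j / c) ** h_j),

the fraction of (virtual) enzyme bound by compound j at concentration ``c``,
and the four-parameter log-logistic (4PLL) readout

    R_j(c) = b + (m_j - b) * o_j(c),

where ``b`` is the baseline readout of the untreated system (shared by every
compound in the experiment, since it refers to the absence of any compound),
``m_j`` the maximal effect, ``i_j`` the half-maximally effective
concentration (EC50) and ``h_j`` the Hill (cooperativity) coefficient.

``m_j`` may lie above, below or at the baseline: full and partial agonists,
inverse agonists (``m_j`` on the opposite side of ``b``) and neutral
antagonists (``m_j == b``, a compound that occupies the site without
producing a response) are all admissible marginals.

Both compounds of a pair are fitted jointly by non-linear least squares
with a single shared baseline; the EC50 is estimated on the natural-log
scale so that it stays positive and so that the standard error of
log(EC50) -- the quantity screened by the quality filter -- can be read
directly off the parameter covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitError",
    "MarginalCurve",
    "MonoData",
    "MarginalFitResult",
    "QCResult",
    "fit_marginals",
    "quality_filter",
    "transform_growth",
]

_ONE_BELOW = float(np.nextafter(1.0, 0.0))
_N_PARAMS = 7  # shared b, plus (m, log ec50, h) per compound


class FitError(RuntimeError):
    """Shared-baseline non-linear least squares failed to converge."""


@dataclass(frozen=True)
class MarginalCurve:
    """One compound's 4PLL concentration-response curve.

    Parameters
    ----------
    b : baseline readout at zero concentration (shared across compounds).
    m : maximal-effect readout (asymptote as c -> infinity).
    ec50 : half-maximally effective concentration, > 0.
    hill : Hill coefficient, > 0.
    """

    b: float
    m: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.b, self.m, self.ec50, self.hill]).all():
            raise ValueError("curve parameters must be finite")
        if not self.ec50 > 0:
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if not self.hill > 0:
            raise ValueError(f"hill must be positive, got {self.hill}")

    @property
    def invertible(self) -> bool:
        """False for a flat curve (m == b), whose readout cannot be inverted."""
        scale = max(abs(self.b), abs(self.m), 1.0)
        return abs(self.m - self.b) > 1e-12 * scale

    def occupancy(self, c):
        """Fraction of enzyme bound at concentration ``c`` (in [0, 1))."""
        c_arr = np.atleast_1d(np.asarray(c, dtype=float))
        if np.any(c_arr < 0) or not np.isfinite(c_arr).all():
            raise ValueError("concentrations must be finite and non-negative")
        o = np.zeros_like(c_arr)
        pos = c_arr > 0
        with np.errstate(over="ignore"):
            o[pos] = 1.0 / (1.0 + (self.ec50 / c_arr[pos]) ** self.hill)
        o = np.minimum(o, _ONE_BELOW)
        return o if np.ndim(c) else float(o[0])

    def readout(self, c):
        """4PLL readout at concentration ``c``; equals ``b`` at c = 0."""
        return self.b + (self.m - self.b) * self.occupancy(c)

    def inverse_conc_from_occupancy(self, o):
        """Concentration producing occupancy ``o``, for 0 < o < 1."""
        o_arr = np.atleast_1d(np.asarray(o, dtype=float))
        if np.any(o_arr <= 0) or np.any(o_arr >= 1):
            raise ValueError("occupancy must lie strictly inside (0, 1)")
        c = self.ec50 * (1.0 / o_arr - 1.0) ** (-1.0 / self.hill)
        return c if np.ndim(o) else float(c[0])

    def inverse_conc_from_readout(self, r):
        """Concentration producing readout ``r`` strictly between b and m."""
        if not self.invertible:
            raise ValueError("flat curve (m == b) is not invertible")
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        lo, hi = sorted((self.b, self.m))
        if np.any(r_arr <= lo) or np.any(r_arr >= hi):
            raise ValueError(
                f"readout must lie strictly between baseline and maximum ({lo}, {hi})"
            )
        c = self.ec50 * ((self.m - self.b) / (r_arr - self.b) - 1.0) ** (-1.0 / self.hill)
        return c if np.ndim(r) else float(c[0])


def transform_growth(readouts, enabled: bool = True) -> np.ndarray:
    """Optional variance-stabilizing pre-processing applied before fitting.

    When enabled, maps raw (strictly positive) growth-type readouts to their
    natural logarithm -- an instantaneous-growth style transform; when
    disabled, returns the readouts unchanged.
    """
    arr = np.asarray(readouts, dtype=float)
    if not enabled:
        return arr.copy()
    if np.any(arr <= 0):
        raise ValueError("growth transform requires strictly positive readouts")
    return np.log(arr)


@dataclass(frozen=True)
class MonoData:
    """Mono-therapy observations for one compound pair.

    ``control_effects`` are untreated (both doses zero) readouts; they inform
    the shared baseline and count as mono-therapy observations.
    """

    doses1: np.ndarray
    effects1: np.ndarray
    doses2: np.ndarray
    effects2: np.ndarray
    control_effects: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for name in ("doses1", "effects1", "doses2", "effects2", "control_effects"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if len(self.doses1) != len(self.effects1) or len(self.doses2) != len(self.effects2):
            raise ValueError("doses and effects must have matching lengths")
        for d in (self.doses1, self.doses2):
            if np.any(d < 0) or not np.isfinite(d).all():
                raise ValueError("doses must be finite and non-negative")
        for y in (self.effects1, self.effects2, self.control_effects):
            if not np.isfinite(y).all():
                raise ValueError("readouts must be finite")

    @property
    def n_obs(self) -> int:
        return len(self.doses1) + len(self.doses2) + len(self.control_effects)


@dataclass(frozen=True)
class MarginalFitResult:
    """Joint shared-baseline 4PLL fit of a compound pair.

    ``covariance`` is the Gauss-Newton parameter covariance in the order
    (b, m1, log_ec50_1, h1, m2, log_ec50_2, h2); ``se_log_ec50`` are the
    square roots of its log-EC50 diagonal entries, the quantities screened
    by :func:`quality_filter`.
    """

    curves: tuple[MarginalCurve, MarginalCurve]
    sigma2: float
    df_residual: int
    se_log_ec50: tuple[float, float]
    covariance: np.ndarray
    n_obs: int
    converged: bool
    message: str = ""

    def to_record(self) -> dict:
        """Flat record of the fit, for CSV/JSON serialization."""
        c1, c2 = self.curves
        return {
            "b": c1.b,
            "m1": c1.m,
            "m2": c2.m,
            "i1": c1.ec50,
            "i2": c2.ec50,
            "h1": c1.hill,
            "h2": c2.hill,
            "sigma2": self.sigma2,
            "df": self.df_residual,
            "se_log_ec50_1": self.se_log_ec50[0],
            "se_log_ec50_2": self.se_log_ec50[1],
            "converged": self.converged,
        }


def _stack(mono: MonoData):
    c = np.concatenate([mono.doses1, mono.doses2, np.zeros(len(mono.control_effects))])
    y = np.concatenate([mono.effects1, mono.effects2, mono.control_effects])
    comp = np.concatenate(
        [
            np.zeros(len(mono.doses1), dtype=int),
            np.ones(len(mono.doses2), dtype=int),
            np.full(len(mono.control_effects), -1, dtype=int),
        ]
    )
    return c, y, comp


def _model(theta: np.ndarray, c: np.ndarray, comp: np.ndarray) -> np.ndarray:
    b = theta[0]
    out = np.full(c.shape, b)
    for j in (0, 1):
        m, li, h = theta[1 + 3 * j : 4 + 3 * j]
        mask = (comp == j) & (c > 0)
        s = np.clip(h * (li - np.log(c[mask])), -700.0, 700.0)
        o = 1.0 / (1.0 + np.exp(s))
        out[mask] = b + (m - b) * o
    return out


def _jacobian(theta: np.ndarray, c: np.ndarray, comp: np.ndarray) -> np.ndarray:
    b = theta[0]
    J = np.zeros((len(c), _N_PARAMS))
    J[:, 0] = 1.0
    for j in (0, 1):
        m, li, h = theta[1 + 3 * j : 4 + 3 * j]
        mask = (comp == j) & (c > 0)
        logc = np.log(c[mask])
        s = np.clip(h * (li - logc), -700.0, 700.0)
        o = 1.0 / (1.0 + np.exp(s))
        oo = o * (1.0 - o)
        base = 1 + 3 * j
        J[mask, 0] = 1.0 - o
        J[mask, base] = o
        J[mask, base + 1] = -(m - b) * h * oo
        J[mask, base + 2] = -(m - b) * (li - logc) * oo
    return J


def _heuristic_start(mono: MonoData) -> np.ndarray:
    if len(mono.control_effects):
        b0 = float(np.mean(mono.control_effects))
    else:
        # anchor the baseline on the least-dosed observations available
        lows = []
        for d, y in ((mono.doses1, mono.effects1), (mono.doses2, mono.effects2)):
            if len(d):
                lows.append(y[np.argmin(d)])
        b0 = float(np.mean(lows))
    theta = np.empty(_N_PARAMS)
    theta[0] = b0
    for j, (d, y) in enumerate(((mono.doses1, mono.effects1), (mono.doses2, mono.effects2))):
        pos = d > 0
        dp, yp = d[pos], y[pos]
        m0 = float(np.mean(yp[dp == dp.max()])) if len(dp) else b0
        half = 0.5 * (b0 + m0)
        i0 = float(dp[np.argmin(np.abs(yp - half))]) if len(dp) else 1.0
        theta[1 + 3 * j] = m0
        theta[2 + 3 * j] = np.log(i0)
        theta[3 + 3 * j] = 1.0
    return theta


def fit_marginals(
    mono: MonoData,
    *,
    start: Sequence[float] | None = None,
    hill_bounds: tuple[float, float] = (0.1, 10.0),
    ec50_span: float = 1e4,
    tol: float = 1e-12,
) -> MarginalFitResult:
    """Fit both marginal 4PLL curves jointly with one shared baseline.

    Minimizes the summed squared readout residuals of both compounds (plus
    untreated controls) over the 7 free parameters. EC50s are optimized on
    the log scale; Hill coefficients are kept inside ``hill_bounds`` to
    avoid pathological slopes on flat data.

    Parameters
    ----------
    mono : mono-therapy observations for the two compounds.
    start : optional full parameter vector (b, m1, log_i1, h1, m2, log_i2, h2)
        to warm-start from (a single local fit is then run, as used by the
        bootstrap refits); by default a heuristic multistart is used.

    Each EC50 is box-constrained to within a factor ``ec50_span`` of the
    compound's tested dose range; this blocks the unidentifiable ridge where
    the maximal effect and the EC50 drift to infinity together when the data
    do not reach the plateau.

    Raises
    ------
    ValueError : fewer observations than the 7 free parameters.
    FitError : the optimizer fails from every start.
    """
    c, y, comp = _stack(mono)
    n = len(y)
    if n <= _N_PARAMS:
        raise ValueError(f"need more than {_N_PARAMS} mono-therapy observations, got {n}")
    for j, d in enumerate((mono.doses1, mono.doses2), start=1):
        if len(np.unique(d[d > 0])) < 3:
            raise ValueError(f"compound {j} needs at least 3 distinct nonzero doses")

    log_span = np.log(ec50_span)
    li_lims = []
    for d in (mono.doses1, mono.doses2):
        pos = d[d > 0]
        li_lims.append((np.log(pos.min()) - log_span, np.log(pos.max()) + log_span))
    lb = np.array([-np.inf, -np.inf, li_lims[0][0], hill_bounds[0], -np.inf, li_lims[1][0], hill_bounds[0]])
    ub = np.array([np.inf, np.inf, li_lims[0][1], hill_bounds[1], np.inf, li_lims[1][1], hill_bounds[1]])

    if start is not None:
        starts = [np.asarray(start, dtype=float)]
    else:
        theta0 = _heuristic_start(mono)
        starts = [theta0]
        for h0 in (0.3, 3.0):
            t = theta0.copy()
            t[[3, 6]] = h0
            starts.append(t)

    y_scale = max(1.0, float(np.max(np.abs(y))))
    best = None
    messages = []
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(
                lambda th: _model(th, c, comp) - y,
                x0,
                jac=lambda th: _jacobian(th, c, comp),
                bounds=(lb, ub),
                method="trf",
                xtol=tol,
                ftol=tol,
                gtol=tol,
                max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - defensive
            messages.append(str(exc))
            continue
        if not res.success:
            messages.append(res.message)
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < (1e-14 * y_scale) ** 2 * n:
            break
    if best is None:
        raise FitError("marginal fit failed from all starts: " + "; ".join(messages))

    theta = best.x
    resid = _model(theta, c, comp) - y
    ssr = float(resid @ resid)
    df = n - _N_PARAMS
    sigma2 = ssr / df

    J = _jacobian(theta, c, comp)
    JTJ = J.T @ J
    # an unidentifiable EC50 (e.g. flat data) yields a singular Gauss-Newton
    # Hessian; report infinite standard errors rather than a spurious zero
    if np.linalg.cond(JTJ) > 1e12:
        cov = np.full((_N_PARAMS, _N_PARAMS), np.nan)
        se = (np.inf, np.inf)
    else:
        cov = sigma2 * np.linalg.inv(JTJ)
        se = (float(np.sqrt(cov[2, 2])), float(np.sqrt(cov[5, 5])))

    curves = (
        MarginalCurve(b=float(theta[0]), m=float(theta[1]), ec50=float(np.exp(theta[2])), hill=float(theta[3])),
        MarginalCurve(b=float(theta[0]), m=float(theta[4]), ec50=float(np.exp(theta[5])), hill=float(theta[6])),
    )
    return MarginalFitResult(
        curves=curves,
        sigma2=sigma2,
        df_residual=df,
        se_log_ec50=se,
        covariance=cov,
        n_obs=n,
        converged=True,
        message=str(best.message),
    )


@dataclass(frozen=True)
class QCResult:
    """Verdict of the log-EC50 precision screen."""

    passed: bool
    reasons: tuple[str, ...]
    se_log_ec50: tuple[float, float]
    threshold: float


def quality_filter(fit: MarginalFitResult, threshold: float = 10.0) -> QCResult:
    """Screen a fitted pair on the precision of its EC50 estimates.

    Passes iff the standard deviation of each compound's log(EC50) estimate
    does not exceed ``threshold`` (inclusive); the fail reasons name the
    offending compound(s).
    """
    se = fit.se_log_ec50
    if any(s is None or np.isnan(s) for s in se):
        raise ValueError("fit carries no usable log-EC50 standard errors")
    reasons = tuple(
        f"compound {j}: sd(log EC50) = {s:.4g} exceeds threshold {threshold:g}"
        for j, s in enumerate(se, start=1)
        if s > threshold
    )
    return QCResult(passed=not reasons, reasons=reasons, se_log_ec50=tuple(se), threshold=threshold)
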