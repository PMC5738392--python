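"""MeanR and MaxR lack-of-fit tests against the generalized Loewe null.

Both tests contrast the replicate-averaged observed off-axis readouts with
the null-surface prediction computed from the fitted marginal curves.  With
deviation vector d (length k), residual variance sigma2 on df degrees of
freedom from the marginal fit, per-point replicate counts n_i, and
prediction covariance Cp (the covariance of the predicted readouts induced
by marginal-parameter estimation uncertainty), the covariance of d under
the null is

    V = sigma2 * diag(1/n_i) + Cp.

MeanR measures the average deviation through the quadratic form

    R = d' V^{-1} d / k,

referred to an F(k, df) distribution under normally distributed residuals
(parametric path) or to a resampled null (bootstrap path).  MaxR studentizes
each point, t_i = d_i / sqrt(V_ii), and takes max_i |t_i|; the reference
distribution of the maximum doubles as the shared per-point threshold, which
is what controls multiplicity while localizing synergy or antagonism to
individual dose combinations.

The bootstrap null regenerates the full two-level randomness of the observed
statistic: each run draws a deviation vector from MVN(0, V) (measurement
noise plus null-surface uncertainty) together with a fresh variance estimate
-- a chi-square resampled sigma2_b = sigma2 * chi2_df / df scaling V as a
whole (Cp is proportional to the residual variance it was estimated under)
and a resampled Cp_b recomputed from a with-replacement draw of the stored
bootstrap prediction samples -- and recomputes the statistic with the run's
own V_b.  Conditioning on the single observed sigma2 and Cp estimates
instead would produce a markedly anticonservative test: the residual degrees
of freedom of an 8x8 board are small, and the max statistic preferentially
selects points whose Cp diagonal entry happens to be underestimated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .boards import Checkerboard
from .loewe import NullSurface, predict_surface
from .marginals import (
    FitError,
    MarginalFitResult,
    MonoData,
    QCResult,
    fit_marginals,
    quality_filter,
    transform_growth,
)

__all__ = [
    "AnalysisConfig",
    "EstimationError",
    "NumericalError",
    "OffAxisDeviations",
    "TestResult",
    "MaxRResult",
    "SynergyResult",
    "compute_deviations",
    "estimate_cp_bootstrap",
    "meanR_test",
    "maxR_test",
    "run_synergy_analysis",
]

SCHEMA_VERSION = 1


class EstimationError(RuntimeError):
    """Too many bootstrap refits failed while estimating Cp."""


class NumericalError(RuntimeError):
    """A covariance matrix stayed singular after regularization."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the full synergy analysis pipeline.

    ``null_method='auto'`` selects the parametric reference when any
    off-axis point carries replicates and the bootstrap otherwise.
    ``decreasing_effect=True`` declares that a lower readout means a
    stronger effect (growth/viability assays), so observed-below-predicted
    deviations are synergy.
    """

    alpha: float = 0.05
    null_method: str = "auto"  # auto | parametric | bootstrap
    n_boot_null: int = 1000
    n_boot_cp: int = 100
    seed: int | None = None
    log_transform: bool = False
    qc_threshold: float = 10.0
    decreasing_effect: bool = True
    cp_max_fail_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.null_method not in ("auto", "parametric", "bootstrap"):
            raise ValueError(f"unknown null_method {self.null_method!r}")


@dataclass(frozen=True)
class OffAxisDeviations:
    """Observed-minus-predicted contrasts at the off-axis points."""

    doses: np.ndarray          # (k, 2)
    observed_mean: np.ndarray  # (k,)
    predicted: np.ndarray      # (k,)
    n_reps: np.ndarray         # (k,) ints
    sigma2: float
    df_residual: int

    def __len__(self) -> int:
        return len(self.predicted)

    @property
    def deviations(self) -> np.ndarray:
        return self.observed_mean - self.predicted


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str


@dataclass(frozen=True)
class MaxRResult(TestResult):
    """MaxR outcome with per-point studentized deviations and calls."""

    t_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold: float = np.inf
    calls: tuple[str, ...] = ()


def compute_deviations(
    board: Checkerboard, surface: NullSurface, fit: MarginalFitResult
) -> OffAxisDeviations:
    """Contrast replicate-averaged off-axis readouts with the null surface.

    The surface must cover exactly the board's off-axis dose combinations,
    in the board's sorted grid order.
    """
    summ = board.off_axis_summary()
    pts = summ[["d1", "d2"]].to_numpy()
    if len(surface) != len(pts) or not np.allclose(surface.doses, pts, rtol=1e-12, atol=0):
        raise ValueError("null surface does not cover the board's off-axis points")
    return OffAxisDeviations(
        doses=pts,
        observed_mean=summ.observed_mean.to_numpy(),
        predicted=np.asarray(surface.predicted, dtype=float),
        n_reps=summ.n_reps.to_numpy(dtype=int),
        sigma2=fit.sigma2,
        df_residual=fit.df_residual,
    )


def _theta_from_fit(fit: MarginalFitResult) -> np.ndarray:
    c1, c2 = fit.curves
    return np.array([c1.b, c1.m, np.log(c1.ec50), c1.hill, c2.m, np.log(c2.ec50), c2.hill])


def estimate_cp_bootstrap(
    mono: MonoData,
    fit: MarginalFitResult,
    grid,
    n_boot: int = 100,
    seed=None,
    *,
    max_fail_frac: float = 0.1,
    return_samples: bool = False,
):
    """Bootstrap covariance of the predicted null readouts (the Cp matrix).

    Parametric residual resampling: fitted mono-therapy values are perturbed
    with centered Gaussian noise of variance sigma2, the shared-baseline fit
    is recomputed (warm-started from the original optimum), and the null
    surface is re-predicted on ``grid``; Cp is the empirical covariance of
    the predictions across resamples.  Deterministic given ``seed``.

    With ``return_samples=True`` also returns the (n_successes, k) matrix of
    bootstrap predictions, which the bootstrap test null resamples to
    propagate the estimation noise of Cp itself.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(fit.sigma2))
    c1, c2 = fit.curves
    f1 = np.asarray(c1.readout(mono.doses1), dtype=float)
    f2 = np.asarray(c2.readout(mono.doses2), dtype=float)
    f0 = np.full(len(mono.control_effects), c1.b)
    theta0 = _theta_from_fit(fit)

    preds = []
    failures = 0
    for _ in range(n_boot):
        pert = MonoData(
            doses1=mono.doses1,
            effects1=f1 + rng.normal(0.0, sd, size=len(f1)),
            doses2=mono.doses2,
            effects2=f2 + rng.normal(0.0, sd, size=len(f2)),
            control_effects=f0 + rng.normal(0.0, sd, size=len(f0)),
        )
        try:
            refit = fit_marginals(pert, start=theta0, tol=1e-10)
            surf = predict_surface(refit.curves, grid)
        except (FitError, ValueError):
            failures += 1
            continue
        preds.append(surf.predicted)
    if failures > max_fail_frac * n_boot or len(preds) < 2:
        raise EstimationError(
            f"{failures}/{n_boot} bootstrap refits failed while estimating Cp"
        )
    P = np.asarray(preds)
    cp = np.atleast_2d(np.cov(P, rowvar=False))
    cp = 0.5 * (cp + cp.T)
    return (cp, P) if return_samples else cp


# ---------------------------------------------------------------------------
# statistic machinery


def _V_matrix(dev: OffAxisDeviations, cp: np.ndarray) -> np.ndarray:
    cp = np.atleast_2d(np.asarray(cp, dtype=float))
    k = len(dev)
    if cp.shape != (k, k):
        raise ValueError(f"Cp must be {k}x{k}")
    return dev.sigma2 * np.diag(1.0 / dev.n_reps) + cp


def _chol_with_reg(V: np.ndarray):
    """Cholesky factor of V, adding a trace-scaled ridge if needed."""
    try:
        return V, np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        pass
    k = V.shape[0]
    ridge = 1e-10 * np.trace(V) / k
    V2 = V + ridge * np.eye(k)
    try:
        return V2, np.linalg.cholesky(V2)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("deviation covariance V is singular after regularization") from exc


def _noise_scale(dev: OffAxisDeviations) -> float:
    return max(
        1.0,
        float(np.max(np.abs(dev.observed_mean), initial=0.0)),
        float(np.max(np.abs(dev.predicted), initial=0.0)),
    )


def _degenerate(dev: OffAxisDeviations, cp: np.ndarray) -> bool:
    """True in the noise-free regime where V carries no usable variance."""
    scale = _noise_scale(dev)
    tiny = (1e-8 * scale) ** 2
    return dev.sigma2 <= tiny and float(np.trace(np.atleast_2d(cp))) <= len(dev) * tiny


def _null_samples(dev, cp, V, L, n_boot: int, rng, method: str, cp_samples=None):
    """Reference samples of the MeanR and MaxR statistics under the null.

    Bootstrap path: per run, d_b ~ MVN(0, V) together with a fresh variance
    estimate -- the whole of V scaled by sigma2_b/sigma2 = chi2_df/df (Cp is
    proportional to the residual variance it was estimated under) and, when
    the bootstrap prediction samples are available, a Cp_b recomputed from a
    with-replacement resample of them -- and the statistics recomputed with
    the run's own V_b (see module docstring).
    Parametric path: only the max statistic needs sampling (MeanR has the
    exact F reference); draws are correlated standard normals from Corr(V),
    studentized by an independent chi-square factor for sigma2 estimation.
    """
    k = len(dev)
    df = dev.df_residual
    if method == "bootstrap":
        D = rng.standard_normal((n_boot, k)) @ L.T
        u = rng.chisquare(df, n_boot) / df
        diag_n = dev.sigma2 / dev.n_reps
        mean_stats = np.empty(n_boot)
        max_stats = np.empty(n_boot)
        for i in range(n_boot):
            if cp_samples is not None and len(cp_samples) >= 2:
                idx = rng.integers(0, len(cp_samples), len(cp_samples))
                cp_b = np.atleast_2d(np.cov(cp_samples[idx], rowvar=False))
            else:
                cp_b = np.atleast_2d(cp)
            Vb = u[i] * (cp_b + np.diag(diag_n))
            Vb, Lb = _chol_with_reg(Vb)
            x = solve_triangular(Lb, D[i], lower=True)
            mean_stats[i] = (x @ x) / k
            max_stats[i] = np.max(np.abs(D[i]) / np.sqrt(np.diag(Vb)))
        return mean_stats, max_stats
    s = np.sqrt(np.diag(V))
    R = V / np.outer(s, s)
    _, LR = _chol_with_reg(R)
    Z = rng.standard_normal((n_boot, k)) @ LR.T
    u = rng.chisquare(df, n_boot) / df
    max_stats = np.max(np.abs(Z), axis=1) / np.sqrt(u)
    return None, max_stats


def _resolve_method(null_method: str) -> str:
    if null_method not in ("parametric", "bootstrap"):
        raise ValueError("null_method must be 'parametric' or 'bootstrap' here")
    return null_method


def meanR_test(
    dev: OffAxisDeviations,
    cp: np.ndarray,
    alpha: float = 0.05,
    null_method: str = "parametric",
    n_boot_null: int = 1000,
    seed=None,
    *,
    cp_samples=None,
) -> TestResult:
    """Average-deviation lack-of-fit test against the null surface.

    Statistic d' V^{-1} d / k; parametric p-value from F(k, df), bootstrap
    p-value as the (r+1)/(B+1) exceedance fraction over resampled nulls.
    ``cp_samples`` (the bootstrap prediction samples behind ``cp``) lets the
    bootstrap null propagate the estimation noise of Cp itself.
    """
    method = _resolve_method(null_method)
    k = len(dev)
    d = dev.deviations
    if _degenerate(dev, cp):
        exact = bool(np.max(np.abs(d), initial=0.0) <= 1e-6 * _noise_scale(dev))
        return TestResult(statistic=0.0 if exact else np.inf, pvalue=1.0 if exact else 0.0, method=method)
    V, L = _chol_with_reg(_V_matrix(dev, cp))
    x = solve_triangular(L, d, lower=True)
    stat = float(x @ x) / k
    if method == "parametric":
        p = float(stats.f.sf(stat, k, dev.df_residual))
    else:
        rng = np.random.default_rng(seed)
        mean_stats, _ = _null_samples(dev, cp, V, L, n_boot_null, rng, "bootstrap", cp_samples)
        p = float((np.sum(mean_stats >= stat) + 1) / (n_boot_null + 1))
    return TestResult(statistic=stat, pvalue=p, method=method)


def maxR_test(
    dev: OffAxisDeviations,
    cp: np.ndarray,
    alpha: float = 0.05,
    null_method: str = "parametric",
    n_boot_null: int = 1000,
    seed=None,
    *,
    decreasing_effect: bool = True,
    cp_samples=None,
) -> MaxRResult:
    """Largest-studentized-deviation test with per-point calls.

    A point is called non-additive when its |t_i| exceeds the (1 - alpha)
    quantile of the null maximum, so the per-point threshold is shared and
    multiplicity-controlled by construction; the direction of each call
    follows the sign of the deviation and the configured effect direction.
    """
    method = _resolve_method(null_method)
    k = len(dev)
    d = dev.deviations

    def direction(di: float) -> str:
        more = (di < 0) if decreasing_effect else (di > 0)
        return "synergy" if more else "antagonism"

    if _degenerate(dev, cp):
        tol = 1e-6 * _noise_scale(dev)
        hit = np.abs(d) > tol
        t = np.where(hit, np.where(d > 0, np.inf, -np.inf), 0.0)
        calls = tuple(direction(di) if h else "additive" for di, h in zip(d, hit))
        stat = float(np.max(np.abs(t), initial=0.0))
        return MaxRResult(
            statistic=stat,
            pvalue=0.0 if hit.any() else 1.0,
            method=method,
            t_values=t,
            threshold=np.inf,
            calls=calls,
        )

    V, L = _chol_with_reg(_V_matrix(dev, cp))
    t = d / np.sqrt(np.diag(V))
    stat = float(np.max(np.abs(t)))
    rng = np.random.default_rng(seed)
    _, max_stats = _null_samples(dev, cp, V, L, n_boot_null, rng, method, cp_samples)
    p = float((np.sum(max_stats >= stat) + 1) / (n_boot_null + 1))
    threshold = float(np.quantile(max_stats, 1.0 - alpha))
    calls = tuple(
        direction(di) if abs(ti) > threshold else "additive" for di, ti in zip(d, t)
    )
    return MaxRResult(
        statistic=stat, pvalue=p, method=method, t_values=t, threshold=threshold, calls=calls
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class SynergyResult:
    """Full outcome of a checkerboard synergy analysis."""

    status: str  # ok | invalidated
    fit: MarginalFitResult
    qc: QCResult
    config: AnalysisConfig
    null_method: str | None = None
    surface: NullSurface | None = None
    deviations: OffAxisDeviations | None = None
    cp: np.ndarray | None = None
    meanR: TestResult | None = None
    maxR: MaxRResult | None = None
    overall_call: str = "invalidated"

    def to_dict(self) -> dict:
        out = {
            "schema_version": SCHEMA_VERSION,
            "status": self.status,
            "marginal_fit": self.fit.to_record(),
            "qc": {"pass": self.qc.passed, "reasons": list(self.qc.reasons)},
            "overall_call": self.overall_call,
            "config": dataclasses.asdict(self.config),
            "seed": self.config.seed,
            "null_method": self.null_method,
            "meanR": None,
            "maxR": None,
        }
        if self.meanR is not None:
            out["meanR"] = {"stat": self.meanR.statistic, "p": self.meanR.pvalue}
        if self.maxR is not None:
            out["maxR"] = {
                "stat": self.maxR.statistic,
                "p": self.maxR.pvalue,
                "threshold": self.maxR.threshold,
                "calls": [
                    {"d1": float(d1), "d2": float(d2), "t": float(t), "call": call}
                    for (d1, d2), t, call in zip(
                        self.deviations.doses, self.maxR.t_values, self.maxR.calls
                    )
                ],
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def points_frame(self):
        """Per-point table (d1, d2, observed_mean, predicted, t_value, call)."""
        import pandas as pd

        if self.deviations is None or self.maxR is None:
            raise ValueError("no per-point results (analysis was invalidated)")
        return pd.DataFrame(
            {
                "d1": self.deviations.doses[:, 0],
                "d2": self.deviations.doses[:, 1],
                "observed_mean": self.deviations.observed_mean,
                "predicted": self.deviations.predicted,
                "t_value": self.maxR.t_values,
                "call": list(self.maxR.calls),
            }
        )


def run_synergy_analysis(board: Checkerboard, config: AnalysisConfig | None = None) -> SynergyResult:
    """Fit, screen, predict and test one checkerboard end to end.

    Stages: optional growth transform; shared-baseline marginal fit; log-EC50
    quality screen (aborting with status ``invalidated`` on failure); null
    surface prediction at the off-axis points; Cp bootstrap; MeanR and MaxR
    at the configured significance level.  All randomness derives from
    ``config.seed``.
    """
    cfg = config if config is not None else AnalysisConfig()
    work = board
    if cfg.log_transform:
        work = board.with_effects(transform_growth(board.data.effect.to_numpy(), enabled=True))

    mono = work.mono_data()
    fit = fit_marginals(mono)
    qc = quality_filter(fit, threshold=cfg.qc_threshold)
    if not qc.passed:
        return SynergyResult(status="invalidated", fit=fit, qc=qc, config=cfg)

    grid = work.off_axis_grid()
    if len(grid) == 0:
        raise ValueError("board has no off-axis dose combinations to test")
    surface = predict_surface(fit.curves, grid)
    dev = compute_deviations(work, surface, fit)

    ss = np.random.SeedSequence(cfg.seed)
    cp_seed, null_seed = ss.spawn(2)
    cp, cp_samples = estimate_cp_bootstrap(
        mono,
        fit,
        grid,
        n_boot=cfg.n_boot_cp,
        seed=cp_seed,
        max_fail_frac=cfg.cp_max_fail_frac,
        return_samples=True,
    )

    method = cfg.null_method
    if method == "auto":
        method = "parametric" if work.has_replicates() else "bootstrap"

    meanr = meanR_test(dev, cp, cfg.alpha, method, cfg.n_boot_null, null_seed, cp_samples=cp_samples)
    maxr = maxR_test(
        dev,
        cp,
        cfg.alpha,
        method,
        cfg.n_boot_null,
        null_seed,
        decreasing_effect=cfg.decreasing_effect,
        cp_samples=cp_samples,
    )

    if meanr.pvalue <= cfg.alpha:
        s = float(np.sum(maxr.t_values)) if np.isfinite(maxr.t_values).all() else float(
            np.sum(np.sign(dev.deviations))
        )
        more = (s < 0) if cfg.decreasing_effect else (s > 0)
        overall = "synergy" if more else "antagonism"
    else:
        overall = "additive"

    return SynergyResult(
        status="ok",
        fit=fit,
        qc=qc,
        config=cfg,
        null_method=method,
        surface=surface,
        deviations=dev,
        cp=cp,
        meanR=meanr,
        maxR=maxr,
        overall_call=overall,
    )
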