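"""Synthetic checkerboard experiments with known ground truth.

The generator emulates a full-factorial two-compound checkerboard: each
compound is laid out as a serial dilution (plus dose zero), mono-therapy
readouts follow the ground-truth 4PLL curves, off-axis readouts follow the
generalized Loewe null prediction plus an optional injected deviation
(synergy when the shift points in the effect direction, antagonism
otherwise), and homoscedastic Gaussian noise is added everywhere --
matching the equal-variance assumption of the lack-of-fit tests.

The default scenario is an 8x8 board (7 two-fold dilutions centered on
each EC50, plus zero) with a full agonist (m = 1.0, EC50 = 1, h = 1) and a
partial agonist (m = 0.6, EC50 = 10, h = 2) over baseline b = 0.1, one
replicate per well and noise SD 0.045 (5% of the full agonist's dynamic
range).  Type-I-error and power studies drive the full analysis pipeline
over many such boards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .boards import Checkerboard
from .loewe import predict_surface
from .marginals import FitError, MarginalCurve
from .synergy import AnalysisConfig, EstimationError, run_synergy_analysis

__all__ = [
    "SimulationSpec",
    "StudyResult",
    "default_curves",
    "default_spec",
    "dilution_series",
    "generate_board",
    "run_typeI_study",
    "run_power_study",
]

DEFAULT_NOISE_SD = 0.045  # 5% of |m1 - b| for the default curves


def default_curves() -> tuple[MarginalCurve, MarginalCurve]:
    """Default ground truth: a full and a partial agonist over b = 0.1."""
    return (
        MarginalCurve(b=0.1, m=1.0, ec50=1.0, hill=1.0),
        MarginalCurve(b=0.1, m=0.6, ec50=10.0, hill=2.0),
    )


def dilution_series(center: float, n: int = 7, factor: float = 2.0) -> np.ndarray:
    """``n``-point serial dilution centered (geometrically) on ``center``."""
    return center * factor ** (np.arange(n) - n // 2).astype(float)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth, grid, noise model and injected deviation for one board.

    ``doses1``/``doses2`` are the nonzero dilution series; dose zero is part
    of every generated board implicitly (untreated well and mono axes).
    ``deviation`` is an additive readout-scale shift applied to every
    off-axis point (scalar) or to selected points (mapping (d1, d2) -> shift);
    zero means the additive null is the truth.
    """

    curves: tuple[MarginalCurve, MarginalCurve] = field(default_factory=default_curves)
    doses1: np.ndarray | None = None
    doses2: np.ndarray | None = None
    n_reps: int = 1
    noise_sd: float = DEFAULT_NOISE_SD
    deviation: float | Mapping = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        d1 = self.doses1 if self.doses1 is not None else dilution_series(self.curves[0].ec50)
        d2 = self.doses2 if self.doses2 is not None else dilution_series(self.curves[1].ec50)
        d1 = np.sort(np.asarray(d1, dtype=float))
        d2 = np.sort(np.asarray(d2, dtype=float))
        for j, d in enumerate((d1, d2), start=1):
            if np.any(d <= 0):
                raise ValueError(f"doses{j} must be strictly positive (dose 0 is implicit)")
            if len(np.unique(d)) < 4:
                raise ValueError(f"doses{j} needs at least 4 distinct nonzero doses")
        object.__setattr__(self, "doses1", d1)
        object.__setattr__(self, "doses2", d2)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        b1, b2 = self.curves[0].b, self.curves[1].b
        if abs(b1 - b2) > 1e-6 * max(1.0, abs(b1)):
            raise ValueError("true curves must share the same baseline")

    # -- serialization for CLI spec files --------------------------------
    def to_dict(self) -> dict:
        dev = self.deviation
        if isinstance(dev, Mapping):
            dev = [[float(k[0]), float(k[1]), float(v)] for k, v in dev.items()]
        return {
            "b": self.curves[0].b,
            "curves": [[c.m, c.ec50, c.hill] for c in self.curves],
            "doses1": list(map(float, self.doses1)),
            "doses2": list(map(float, self.doses2)),
            "n_reps": self.n_reps,
            "noise_sd": self.noise_sd,
            "deviation": dev,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationSpec":
        b = float(d.get("b", 0.1))
        raw_curves = d.get("curves")
        if raw_curves is not None:
            curves = tuple(MarginalCurve(b=b, m=m, ec50=i, hill=h) for m, i, h in raw_curves)
        else:
            curves = default_curves()
        dev = d.get("deviation", 0.0)
        if isinstance(dev, list):
            dev = {(row[0], row[1]): row[2] for row in dev}
        return cls(
            curves=curves,
            doses1=d.get("doses1"),
            doses2=d.get("doses2"),
            n_reps=int(d.get("n_reps", 1)),
            noise_sd=float(d.get("noise_sd", DEFAULT_NOISE_SD)),
            deviation=dev,
            seed=int(d.get("seed", 0)),
        )


def default_spec(**overrides) -> SimulationSpec:
    """The default 8x8 study scenario, with field overrides."""
    return SimulationSpec(**overrides)


def _deviation_vector(spec: SimulationSpec, grid: np.ndarray) -> np.ndarray:
    if isinstance(spec.deviation, Mapping):
        dv = np.zeros(len(grid))
        for (d1, d2), shift in spec.deviation.items():
            match = np.isclose(grid[:, 0], d1) & np.isclose(grid[:, 1], d2)
            if not match.any():
                raise ValueError(f"deviation key ({d1}, {d2}) matches no off-axis point")
            dv[match] = shift
        return dv
    return np.full(len(grid), float(spec.deviation))


def generate_board(spec: SimulationSpec) -> Checkerboard:
    """Draw one synthetic checkerboard from the spec; deterministic per seed.

    Mono-therapy readouts are the true 4PLL values, off-axis readouts the
    generalized-Loewe prediction plus the injected deviation; Gaussian noise
    of SD ``noise_sd`` is added to every well.
    """
    c1, c2 = spec.curves
    d1_axis = np.concatenate([[0.0], spec.doses1])
    d2_axis = np.concatenate([[0.0], spec.doses2])
    D1, D2 = np.meshgrid(d1_axis, d2_axis, indexing="ij")
    d1 = D1.ravel()
    d2 = D2.ravel()

    base = np.empty_like(d1)
    untreated = (d1 == 0) & (d2 == 0)
    m1 = (d1 > 0) & (d2 == 0)
    m2 = (d1 == 0) & (d2 > 0)
    off = (d1 > 0) & (d2 > 0)
    base[untreated] = c1.b
    base[m1] = c1.readout(d1[m1])
    base[m2] = c2.readout(d2[m2])
    grid = np.column_stack([d1[off], d2[off]])
    base[off] = predict_surface((c1, c2), grid).predicted + _deviation_vector(spec, grid)

    # replicate and sort rows so the noise stream is tied to a fixed layout
    df = pd.DataFrame(
        {
            "d1": np.tile(d1, spec.n_reps),
            "d2": np.tile(d2, spec.n_reps),
            "effect": np.tile(base, spec.n_reps),
            "replicate": np.repeat(np.arange(1, spec.n_reps + 1), len(d1)),
        }
    ).sort_values(["d1", "d2", "replicate"], ignore_index=True)

    rng = np.random.default_rng(spec.seed)
    df["effect"] = df["effect"].to_numpy() + rng.normal(0.0, spec.noise_sd, size=len(df))
    return Checkerboard.from_dataframe(df)


@dataclass(frozen=True)
class StudyResult:
    """Summary table plus per-simulation p-values of a simulation study."""

    summary: pd.DataFrame
    details: pd.DataFrame

    def rate(self, test: str, deviation: float | None = None) -> float:
        s = self.summary
        if deviation is not None and "deviation" in s.columns:
            s = s[np.isclose(s.deviation, deviation)]
        return float(s.loc[s.test == test, "rate"].iloc[0])


def _run_batch(
    spec: SimulationSpec, n_sims: int, alpha: float, config: AnalysisConfig, seed0: int
) -> pd.DataFrame:
    rows = []
    for i in range(n_sims):
        board_seed = int(seed0) + i
        s = replace(spec, seed=board_seed)
        board = generate_board(s)
        cfg = replace(config, alpha=alpha, seed=board_seed)
        try:
            res = run_synergy_analysis(board, cfg)
        except (FitError, EstimationError) as exc:
            rows.append({"sim": i, "seed": board_seed, "status": f"failed: {exc}",
                         "meanR_p": np.nan, "maxR_p": np.nan})
            continue
        if res.status != "ok":
            rows.append({"sim": i, "seed": board_seed, "status": res.status,
                         "meanR_p": np.nan, "maxR_p": np.nan})
            continue
        rows.append(
            {
                "sim": i,
                "seed": board_seed,
                "status": "ok",
                "meanR_p": res.meanR.pvalue,
                "maxR_p": res.maxR.pvalue,
            }
        )
    return pd.DataFrame(rows)


def _summarize(details: pd.DataFrame, n_sims: int, alpha: float) -> pd.DataFrame:
    ok = details[details.status == "ok"]
    rows = []
    for test in ("MeanR", "MaxR"):
        p = ok["meanR_p"] if test == "MeanR" else ok["maxR_p"]
        rej = int((p <= alpha).sum())
        n_ok = len(ok)
        lo, hi = proportion_confint(rej, max(n_ok, 1), alpha=0.05, method="wilson")
        rows.append(
            {
                "test": test,
                "n_sims": n_sims,
                "n_excluded": n_sims - n_ok,
                "rejections": rej,
                "rate": rej / n_ok if n_ok else np.nan,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def run_typeI_study(
    spec: SimulationSpec,
    n_sims: int = 500,
    alpha: float = 0.05,
    config: AnalysisConfig | None = None,
) -> StudyResult:
    """Rejection rates of MeanR and MaxR over additive (null-true) boards.

    Board ``i`` uses seed ``spec.seed + i``; failed or invalidated fits are
    counted and excluded from the denominator.  The spec's deviation is
    forced to zero.
    """
    cfg = config if config is not None else AnalysisConfig()
    null_spec = replace(spec, deviation=0.0)
    details = _run_batch(null_spec, n_sims, alpha, cfg, seed0=spec.seed)
    return StudyResult(summary=_summarize(details, n_sims, alpha), details=details)


def run_power_study(
    spec: SimulationSpec,
    deviations,
    n_sims: int = 100,
    alpha: float = 0.05,
    config: AnalysisConfig | None = None,
) -> StudyResult:
    """Rejection rates across a grid of injected deviation magnitudes.

    Each magnitude gets its own block of ``n_sims`` boards with disjoint
    seed ranges so the blocks are independent.
    """
    cfg = config if config is not None else AnalysisConfig()
    summaries = []
    all_details = []
    for idx, dv in enumerate(deviations):
        s = replace(spec, deviation=float(dv))
        details = _run_batch(s, n_sims, alpha, cfg, seed0=spec.seed + idx * n_sims)
        details = details.assign(deviation=float(dv))
        summary = _summarize(details, n_sims, alpha).assign(deviation=float(dv))
        summaries.append(summary)
        all_details.append(details)
    return StudyResult(
        summary=pd.concat(summaries, ignore_index=True),
        details=pd.concat(all_details, ignore_index=True),
    )
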