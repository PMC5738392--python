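"""Checkerboard containers and the long-format CSV dialect.

A checkerboard combination experiment is stored in long format with one row
per well: columns ``d1`` and ``d2`` (non-negative doses of the two
compounds), ``effect`` (the readout) and an optional ``replicate`` id.
Rows with exactly one zero dose are mono-therapy points, rows with both
doses zero are untreated controls, and rows with both doses positive are
the off-axis combination points tested against the null surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marginals import MonoData

__all__ = ["ParseError", "Checkerboard", "read_board", "write_board"]

REQUIRED_COLUMNS = ("d1", "d2", "effect")


class ParseError(ValueError):
    """A board file or frame violates the long-format dialect."""


@dataclass(frozen=True)
class Checkerboard:
    """Validated long-format checkerboard data with derived views."""

    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source: str = "<data>") -> "Checkerboard":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{source}: missing required column(s) {missing}")
        out = df.copy().reset_index(drop=True)
        for col in REQUIRED_COLUMNS:
            values = pd.to_numeric(out[col], errors="coerce")
            bad = values.isna() | ~np.isfinite(values)
            if bad.any():
                row = int(bad.idxmax())
                raise ParseError(f"{source}: non-numeric or non-finite value in column '{col}', row {row}")
            out[col] = values.astype(float)
        for col in ("d1", "d2"):
            neg = out[col] < 0
            if neg.any():
                row = int(neg.idxmax())
                raise ParseError(f"{source}: negative dose in column '{col}', row {row}")
        if "replicate" not in out.columns:
            out["replicate"] = out.groupby(["d1", "d2"]).cumcount() + 1
        return cls(data=out)

    # ---- derived views -------------------------------------------------
    @property
    def mono1(self) -> pd.DataFrame:
        d = self.data
        return d[(d.d1 > 0) & (d.d2 == 0)]

    @property
    def mono2(self) -> pd.DataFrame:
        d = self.data
        return d[(d.d1 == 0) & (d.d2 > 0)]

    @property
    def untreated(self) -> pd.DataFrame:
        d = self.data
        return d[(d.d1 == 0) & (d.d2 == 0)]

    @property
    def off_axis(self) -> pd.DataFrame:
        d = self.data
        return d[(d.d1 > 0) & (d.d2 > 0)]

    # ---- accessors -----------------------------------------------------
    def mono_data(self) -> MonoData:
        """Mono-therapy observations (plus untreated controls) for fitting."""
        return MonoData(
            doses1=self.mono1.d1.to_numpy(),
            effects1=self.mono1.effect.to_numpy(),
            doses2=self.mono2.d2.to_numpy(),
            effects2=self.mono2.effect.to_numpy(),
            control_effects=self.untreated.effect.to_numpy(),
        )

    def off_axis_summary(self) -> pd.DataFrame:
        """Replicate-averaged off-axis readouts, sorted by (d1, d2)."""
        g = self.off_axis.groupby(["d1", "d2"], sort=True)["effect"]
        out = g.agg(observed_mean="mean", n_reps="count").reset_index()
        return out

    def off_axis_grid(self) -> np.ndarray:
        """Unique off-axis dose combinations as a (k, 2) array, sorted."""
        return self.off_axis_summary()[["d1", "d2"]].to_numpy()

    def has_replicates(self) -> bool:
        """True when any off-axis dose combination carries >= 2 replicates."""
        if self.off_axis.empty:
            return False
        return bool((self.off_axis_summary().n_reps >= 2).any())

    def with_effects(self, effects: np.ndarray) -> "Checkerboard":
        """Copy of the board with a replaced effect column (row order kept)."""
        out = self.data.copy()
        out["effect"] = np.asarray(effects, dtype=float)
        return Checkerboard(data=out)


def read_board(path) -> Checkerboard:
    """Read a long-format board CSV (header d1,d2,effect[,replicate])."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return Checkerboard.from_dataframe(df, source=str(path))


def write_board(board: Checkerboard, path) -> None:
    """Write a board in the same CSV dialect, preserving full precision."""
    board.data.to_csv(path, index=False)
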