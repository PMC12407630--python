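"""Quantitative relative time-series data (EXP dialect) and the Gaussian
likelihood over it.

Measurements are relative intensities scaled into (0, 1]; the model output
for a cell (time, observable) is the corresponding absolute abundance
multiplied by an adjustable positive scale factor. Missing cells are written
as "nan" and contribute nothing to the fit.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reaction_model import Trajectory, observable_series

__all__ = [
    "QuantTable",
    "parse_exp",
    "write_exp",
    "quant_sse",
    "gaussian_neg_loglik",
    "residuals",
]


@dataclass(frozen=True)
class QuantTable:
    """Relative time-series table: rows = times (s), columns = observables."""

    data: pd.DataFrame  # float values, NaN = missing

    def __post_init__(self):
        t = self.data.index.to_numpy(dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def observables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        """Number of non-missing measurements."""
        return int(self.data.notna().to_numpy().sum())

    def range_violations(self) -> list[tuple[float, str, float]]:
        """Cells whose values fall outside (0, 1] (parsing accepts them;
        validation flags them)."""
        bad = []
        for t in self.data.index:
            for col in self.data.columns:
                y = self.data.at[t, col]
                if pd.notna(y) and not (0.0 < y <= 1.0):
                    bad.append((float(t), str(col), float(y)))
        return bad


def parse_exp(text: str) -> QuantTable:
    """Parse an EXP-dialect tab-delimited table.

    First column holds times, the header row names observables, and "nan"
    marks a missing measurement. Raises on non-numeric cells and duplicate
    times.
    """
    stripped = text.strip()
    if not stripped:
        return QuantTable(pd.DataFrame(index=pd.Index([], dtype=float)))
    df = pd.read_csv(io.StringIO(text), sep=r"\s+", index_col=0)
    header = [str(c) for c in df.columns]
    df.columns = header
    if len(df.index) and not df.index.is_unique:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate time row(s): {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.lower() != "nan")
        if bad.any():
            t = df.index[bad][0]
            raise ValueError(f"non-numeric cell at time {t}, column {col!r}")
        df[col] = coerced
    df.index = pd.to_numeric(df.index)
    df = df.sort_index()
    return QuantTable(df.astype(float))


def write_exp(table: QuantTable, time_label: str = "time") -> str:
    """Serialize to EXP dialect (tab-delimited, "nan" for missing cells)."""
    lines = ["\t".join([time_label, *table.observables])]
    for t in table.data.index:
        cells = [f"{float(t):g}"]
        for col in table.observables:
            y = table.data.at[t, col]
            cells.append("nan" if pd.isna(y) else f"{float(y):.6g}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def _scaled_outputs(table: QuantTable, traj: Trajectory,
                    scales: dict[str, float]) -> pd.DataFrame:
    for name, s in scales.items():
        if not s > 0:
            raise ValueError(f"scale factor {name!r} must be positive")
    out = {}
    for col in table.observables:
        if col not in scales:
            raise KeyError(f"no scale factor for observable {col!r}")
        series = observable_series(traj, col)
        idx = [traj.time_index(t) for t in table.times]
        out[col] = scales[col] * series[idx]
    return pd.DataFrame(out, index=table.data.index)


def residuals(table: QuantTable, traj: Trajectory,
              scales: dict[str, float]) -> pd.DataFrame:
    """Per-cell residuals y - scale * f (NaN where data are missing)."""
    return table.data - _scaled_outputs(table, traj, scales)


def quant_sse(table: QuantTable, traj: Trajectory,
              scales: dict[str, float]) -> float:
    """Sum of squared residuals over the non-missing cells (Fquant)."""
    if table.n == 0:
        return 0.0
    r = residuals(table, traj, scales).to_numpy()
    return float(np.nansum(r * r))


def gaussian_neg_loglik(table: QuantTable, traj: Trajectory,
                        scales: dict[str, float], sigma: float) -> float:
    """Homoscedastic Gaussian negative log-likelihood:

    (n/2) ln(2 pi sigma^2) + Fquant / (2 sigma^2), with the empty-table
    convention that n = 0 gives 0.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    n = table.n
    if n == 0:
        return 0.0
    sse = quant_sse(table, traj, scales)
    return 0.5 * n * math.log(2.0 * math.pi * sigma * sigma) + sse / (2.0 * sigma * sigma)
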