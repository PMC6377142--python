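"""Core data structures, expression-matrix I/O, and series preprocessing.

An :class:`ExpressionDataset` holds a genes x replicates x time tensor on a
uniform hour grid for one experimental condition.  Two file dialects are
supported:

* **wide** — one row per gene, header cells ``<condition>:<replicate>:<time_h>``
  (condition part optional, e.g. ``r1:4.0``);
* **long** — columns ``gene, condition, replicate, time_h, value``.

Expression values are consumed as-is (typically log-scale normalized
intensities); no rescaling is applied unless explicitly requested.
All times are hours and all rate parameters downstream are per hour.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "AnalysisConfig",
    "GridError",
    "ExpressionParseError",
    "read_expression",
    "write_expression",
    "average_replicates",
    "detrend",
]


class GridError(ValueError):
    """Raised when a time grid is not strictly increasing and uniform."""


class ExpressionParseError(ValueError):
    """Raised when an expression file cannot be parsed."""


def _check_uniform_grid(times: np.ndarray, rtol: float = 1e-9) -> float:
    """Validate a strictly increasing uniform grid and return its step."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 3:
        raise GridError(f"need >=3 time points, got {times.size}")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise GridError("times must be strictly increasing")
    dt = steps[0]
    if np.any(np.abs(steps - dt) > rtol * max(abs(dt), 1.0)):
        raise GridError(f"non-uniform time grid: steps {steps.tolist()}")
    return float(dt)


@dataclass(frozen=True)
class ExpressionDataset:
    """Gene x replicate x time expression tensor for one condition.

    Parameters
    ----------
    gene_ids
        Unique gene/probe identifiers, one per tensor row.
    times
        Sampling times in hours; strictly increasing, uniform step.
    values
        Array of shape ``(n_genes, n_replicates, n_times)``; all finite.
    condition
        Label of the experimental condition (e.g. ``"untreated"``).
    """

    gene_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        _check_uniform_grid(times)
        if values.ndim != 3:
            raise ValueError(f"values must be 3-d (gene, replicate, time), got shape {values.shape}")
        if values.shape[0] != len(self.gene_ids):
            raise ValueError("values first axis must match gene_ids")
        if values.shape[2] != times.size:
            raise ValueError("values last axis must match times")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_replicates(self) -> int:
        return int(self.values.shape[1])

    @property
    def dt(self) -> float:
        """Uniform sampling step in hours."""
        return float(self.times[1] - self.times[0])

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def replicates(self, gene: str) -> np.ndarray:
        """Replicate series for one gene, shape (n_replicates, n_times)."""
        return self.values[self.gene_index(gene)]

    def subset(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionDataset(
            gene_ids=tuple(genes),
            times=self.times,
            values=self.values[idx],
            condition=self.condition,
        )

    def metadata(self) -> dict:
        return {
            "condition": self.condition,
            "n_genes": self.n_genes,
            "n_replicates": self.n_replicates,
            "times_h": self.times.tolist(),
        }


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the pipeline.

    Defaults follow the reference analysis: pseudo-sine periods searched in
    12-36 h, rhythm band 18-32 h, link-validation fitness threshold 46 %,
    strict/hub thresholds 80 %/60 %, and 0.2 as the nu-gap significance
    guide.
    """

    period_range: tuple[float, float] = (12.0, 36.0)
    rhythm_band: tuple[float, float] = (18.0, 32.0)
    fit_threshold_pct: float = 46.0
    strict_fit_threshold_pct: float = 80.0
    hub_fit_threshold_pct: float = 60.0
    nugap_threshold: float = 0.2
    grid_step_hours: float = 0.2
    phase_grid_size: int = 64
    freq_grid_size: int = 2000
    local_band: tuple[float, float] = (18.0, 32.0)  # periods, hours
    n_fft: int = 256
    n_restarts: int = 8
    input_hold: str = "foh"  # "foh" | "zoh"
    fitness_sqrt: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        p_min, p_max = self.period_range
        if not p_min < p_max:
            raise ValueError("period_range must satisfy p_min < p_max")
        for name in ("fit_threshold_pct", "strict_fit_threshold_pct", "hub_fit_threshold_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not 0.0 <= self.nugap_threshold <= 1.0:
            raise ValueError("nugap_threshold must be in [0, 1]")
        if self.input_hold not in ("foh", "zoh"):
            raise ValueError("input_hold must be 'foh' or 'zoh'")

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# I/O


def _parse_wide_header(cols: Sequence[str]) -> tuple[list[str | None], list[int], list[float]]:
    conditions: list[str | None] = []
    reps: list[int] = []
    times: list[float] = []
    for col in cols:
        parts = str(col).split(":")
        try:
            if len(parts) == 3:
                cond, rep, t = parts[0], parts[1], parts[2]
            elif len(parts) == 2:
                cond, rep, t = None, parts[0], parts[1]
            else:
                raise ValueError
            rep_i = int(str(rep).lstrip("rR"))
            times.append(float(t))
            reps.append(rep_i)
            conditions.append(cond)
        except ValueError:
            raise ExpressionParseError(
                f"cannot parse column header {col!r}; expected '<condition>:<replicate>:<time_h>'"
            ) from None
    return conditions, reps, times


def read_expression(path: str | Path, dialect: str = "auto", sep: str | None = None) -> ExpressionDataset:
    """Read an expression matrix from a TSV/CSV file.

    Parameters
    ----------
    path
        File with one header row.  Wide dialect: first column gene ids,
        remaining headers ``<condition>:<replicate>:<time_h>``.  Long
        dialect: columns ``gene, condition, replicate, time_h, value``.
    dialect
        ``"wide"``, ``"long"`` or ``"auto"`` (detect from the header).
    sep
        Field separator; inferred from the extension when omitted
        (``.csv`` -> comma, otherwise tab).

    Raises
    ------
    ExpressionParseError
        On missing or non-numeric cells (the offending row/column is named).
    GridError
        If the time grid is not uniform.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ExpressionParseError(f"{path}: expected at least 2 columns")
    long_cols = {"gene", "replicate", "time_h", "value"}
    if dialect == "auto":
        dialect = "long" if long_cols.issubset(set(df.columns)) else "wide"

    if dialect == "long":
        missing = long_cols - set(df.columns)
        if missing:
            raise ExpressionParseError(f"{path}: long dialect missing columns {sorted(missing)}")
        cond_col = df["condition"] if "condition" in df.columns else pd.Series([""] * len(df))
        conds = sorted(set(cond_col))
        if len(conds) != 1:
            raise ExpressionParseError(f"{path}: expected a single condition per file, got {conds}")
        try:
            values = df["value"].astype(float)
            times_col = df["time_h"].astype(float)
            reps_col = df["replicate"].astype(int)
        except ValueError as exc:
            raise ExpressionParseError(f"{path}: non-numeric cell in long table: {exc}") from None
        tidy = pd.DataFrame(
            {"gene": df["gene"], "replicate": reps_col, "time_h": times_col, "value": values}
        )
        genes = list(dict.fromkeys(tidy["gene"]))
        times = np.array(sorted(set(tidy["time_h"])))
        reps = sorted(set(tidy["replicate"]))
        tensor = np.full((len(genes), len(reps), times.size), np.nan)
        g_idx = {g: i for i, g in enumerate(genes)}
        r_idx = {r: i for i, r in enumerate(reps)}
        t_idx = {t: i for i, t in enumerate(times)}
        for row in tidy.itertuples(index=False):
            tensor[g_idx[row.gene], r_idx[row.replicate], t_idx[row.time_h]] = row.value
        if np.any(np.isnan(tensor)):
            g, r, t = np.argwhere(np.isnan(tensor))[0]
            raise ExpressionParseError(
                f"{path}: missing value for gene {genes[g]!r}, replicate {reps[r]}, t={times[t]}"
            )
        return ExpressionDataset(tuple(genes), times, tensor, condition=conds[0])

    # wide dialect
    gene_col = df.columns[0]
    conditions, reps, times_flat = _parse_wide_header(df.columns[1:])
    conds = sorted({c for c in conditions if c is not None})
    if len(conds) > 1:
        raise ExpressionParseError(f"{path}: multiple conditions in one file: {conds}")
    condition = conds[0] if conds else ""
    genes = df[gene_col].tolist()
    uniq_times = sorted(set(times_flat))
    uniq_reps = sorted(set(reps))
    tensor = np.full((len(genes), len(uniq_reps), len(uniq_times)), np.nan)
    r_idx = {r: i for i, r in enumerate(uniq_reps)}
    t_idx = {t: i for i, t in enumerate(uniq_times)}
    for j, col in enumerate(df.columns[1:]):
        try:
            colvals = df[col].astype(float).to_numpy()
        except ValueError:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ExpressionParseError(
                f"{path}: non-numeric cell at row {bad + 2}, column {col!r}"
            ) from None
        tensor[:, r_idx[reps[j]], t_idx[times_flat[j]]] = colvals
    if np.any(np.isnan(tensor)):
        g, r, t = np.argwhere(np.isnan(tensor))[0]
        raise ExpressionParseError(
            f"{path}: missing cell for gene {genes[g]!r}, replicate {uniq_reps[r]}, t={uniq_times[t]}"
        )
    return ExpressionDataset(tuple(genes), np.array(uniq_times, float), tensor, condition=condition)


def write_expression(ds: ExpressionDataset, path: str | Path, sep: str | None = None,
                     sidecar: bool = False) -> None:
    """Write a dataset in the wide dialect; round-trips through read_expression.

    With ``sidecar=True`` a ``<path>.meta.json`` metadata file is written.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    cols: dict[str, np.ndarray] = {}
    prefix = f"{ds.condition}:" if ds.condition else ""
    for r in range(ds.n_replicates):
        for t_i, t in enumerate(ds.times):
            cols[f"{prefix}{r + 1}:{t:g}"] = ds.values[:, r, t_i]
    out = pd.DataFrame({"gene": list(ds.gene_ids), **cols})
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")
    if sidecar:
        Path(str(path) + ".meta.json").write_text(json.dumps(ds.metadata(), indent=1))


def drop_incomplete_genes(gene_ids: Sequence[str], values: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Drop genes containing non-finite entries, logging a warning per drop."""
    keep = []
    for i, g in enumerate(gene_ids):
        if np.all(np.isfinite(values[i])):
            keep.append(i)
        else:
            logger.warning("dropping gene %s: missing/non-finite values", g)
    return [gene_ids[i] for i in keep], values[keep]


# ---------------------------------------------------------------------------
# Preprocessing


def average_replicates(ds: ExpressionDataset, gene: str) -> np.ndarray:
    """Arithmetic mean of the replicate series of one gene, per time point."""
    return ds.replicates(gene).mean(axis=0)


def detrend(series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Remove the ordinary-least-squares straight line from a series.

    The result has zero mean and zero OLS slope; idempotent to rounding.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size != times.size:
        raise ValueError("series and times must have equal length")
    if series.size < 2:
        raise ValueError("need >=2 points to detrend")
    coeffs = np.polynomial.polynomial.polyfit(times, series, 1)
    return series - np.polynomial.polynomial.polyval(times, coeffs)
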