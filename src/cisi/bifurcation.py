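"""Parameter sweeps producing stable/unstable equilibrium branch tables."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .equilibria import (
    base_equilibria,
    nkctl_equilibria,
    saturation_equilibria,
)
from .models import BaseParams, NkCtlParams, SaturationParams

__all__ = ["BranchTable", "sweep", "detect_bifurcations", "default_k_grid"]


@dataclass
class BranchTable:
    """Equilibria of a model along a 1-D parameter sweep.

    ``records[i]`` is the list of ``(T_star, stability)`` pairs (sorted by
    T*) at ``grid[i]``; ``b`` is the inverse carrying capacity used to scale
    tumor sizes to the dimensionless bT*.  ``failed[i]`` is True where the
    equilibrium computation raised (the sweep continues past failures).
    """

    sweep_param: str
    grid: np.ndarray
    records: list
    b: float
    failed: list

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or len(g) != len(self.records):
            raise ValueError("grid/records length mismatch")
        if len(g) > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("sweep grid must be strictly increasing")
        self.grid = g

    def counts(self) -> np.ndarray:
        """Number of distinct equilibria at each grid point."""
        return np.array([len(r) for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (param_value, T_star, bT_star, stability)."""
        rows = []
        for g, rec in zip(self.grid, self.records):
            for T, stab in rec:
                rows.append(
                    {
                        "param_value": g,
                        "T_star": T,
                        "bT_star": self.b * T,
                        "stability": stab,
                    }
                )
        return pd.DataFrame(rows, columns=["param_value", "T_star", "bT_star", "stability"])


def _equilibria_fn(params):
    if isinstance(params, BaseParams):
        return base_equilibria
    if isinstance(params, SaturationParams):
        return saturation_equilibria
    if isinstance(params, NkCtlParams):
        return nkctl_equilibria
    raise TypeError(f"unknown parameter type {type(params)!r}")


def sweep(params, param_name: str, grid) -> BranchTable:
    """Compute equilibria at every value of ``param_name`` along ``grid``.

    Failures at individual grid points are recorded (empty record, flagged)
    and do not abort the sweep.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or not np.all(np.isfinite(grid)):
        raise ValueError("grid must be a finite, non-empty 1-D array")
    fn = _equilibria_fn(params)
    records, failed = [], []
    for value in grid:
        try:
            eqs = fn(replace(params, **{param_name: float(value)}))
            records.append([(eq.T, eq.stability) for eq in eqs])
            failed.append(False)
        except Exception:
            records.append([])
            failed.append(True)
    return BranchTable(
        sweep_param=param_name, grid=grid, records=records, b=params.b, failed=failed
    )


def detect_bifurcations(table: BranchTable) -> list[tuple[tuple[float, float], tuple[int, int]]]:
    """Grid intervals across which the number of distinct equilibria changes.

    Returns a list of ``((g_lo, g_hi), (count_lo, count_hi))``; failed grid
    points are skipped.
    """
    if len(table.grid) < 2:
        raise ValueError("need at least 2 grid points")
    ok = [i for i, f in enumerate(table.failed) if not f]
    counts = table.counts()
    out = []
    for i, j in zip(ok[:-1], ok[1:]):
        if counts[i] != counts[j]:
            out.append(
                (
                    (float(table.grid[i]), float(table.grid[j])),
                    (int(counts[i]), int(counts[j])),
                )
            )
    return out


def default_k_grid(k_min: float = 1e-4, k_max: float = 10.0, n: int = 200) -> np.ndarray:
    """Log-spaced killing-efficacy grid spanning the plausible range."""
    return np.geomspace(k_min, k_max, n)
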