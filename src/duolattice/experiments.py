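"""Experiment drivers: temptation sweeps, amplitude sweeps,
time courses and patch-seeded runs, with replicate aggregation.

Replicate r of a sweep point runs with ``seed = base.seed + r`` and a fresh
coupling field and fresh initial grids, so sweeps are bit-reproducible from
the base seed.  A sweep row reports the replicate mean and standard error
of the stationary cooperation fraction together with per-layer and
pair-fraction means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import SimConfig, run_simulation
from .observables import StationaryStats, TimeSeries, stationary_average

__all__ = [
    "EXTINCTION_THRESHOLD",
    "sweep_b",
    "sweep_A",
    "time_course",
    "patch_experiment",
    "PatchOutcome",
    "estimate_bc",
]

# stationary mean F_C at or below this counts as extinct cooperation
EXTINCTION_THRESHOLD = 0.005


def _replicate_stats(config: SimConfig, replicates: int) -> List[StationaryStats]:
    stats = []
    for r in range(replicates):
        series, _ = run_simulation(config.replace(seed=config.seed + r))
        stats.append(stationary_average(series, config.mcs_measure))
    return stats


def _aggregate(param_name: str, value: float, stats: Sequence[StationaryStats]) -> dict:
    fc = np.array([s.fc_mean for s in stats])
    n = len(stats)
    se = float(fc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        param_name: value,
        "n_replicates": n,
        "fc_mean": float(fc.mean()),
        "fc_se": se,
        "fc_upper_mean": float(np.mean([s.fc_upper for s in stats])),
        "fc_lower_mean": float(np.mean([s.fc_lower for s in stats])),
        "f_cc_mean": float(np.mean([s.f_cc for s in stats])),
    }


def sweep_b(
    base: SimConfig, b_grid: Iterable[float], replicates: int = 10
) -> pd.DataFrame:
    """Stationary F_C versus the temptation b at fixed amplitude A."""
    b_grid = list(b_grid)
    if not b_grid:
        raise ValueError("b_grid is empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for b in b_grid:
        stats = _replicate_stats(base.replace(b=b), replicates)
        rows.append(_aggregate("b", b, stats))
    return pd.DataFrame(rows)


def sweep_A(
    base: SimConfig, A_grid: Iterable[float], replicates: int = 10
) -> pd.DataFrame:
    """Stationary F_C versus the coupling amplitude A at fixed temptation b."""
    A_grid = list(A_grid)
    if not A_grid:
        raise ValueError("A_grid is empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for A in A_grid:
        stats = _replicate_stats(base.replace(A=A), replicates)
        rows.append(_aggregate("A", A, stats))
    return pd.DataFrame(rows)


def time_course(config: SimConfig) -> TimeSeries:
    """Full per-MCS trajectory of one run (for Fc_upper/Fc_lower/f_CC plots)."""
    series, _ = run_simulation(config)
    return series


@dataclass(frozen=True)
class PatchOutcome:
    """Result of a centered-cooperator-patch run."""

    verdict: str  # "persisted" | "extinct"
    stats: StationaryStats
    series: TimeSeries

    @property
    def persisted(self) -> bool:
        return self.verdict == "persisted"


def patch_experiment(base: SimConfig, layers: str = "both") -> PatchOutcome:
    """Run from a centered cooperator patch on the selected layer(s).

    The verdict is "persisted" iff the stationary mean F_C exceeds the
    extinction threshold.
    """
    config = base.replace(init="patch", patch_layers=layers)
    series, _ = run_simulation(config)
    stats = stationary_average(series, config.mcs_measure)
    verdict = "persisted" if stats.fc_mean > EXTINCTION_THRESHOLD else "extinct"
    return PatchOutcome(verdict=verdict, stats=stats, series=series)


def estimate_bc(
    table: pd.DataFrame, threshold: float = EXTINCTION_THRESHOLD
) -> Optional[dict]:
    """Extinction threshold b_c from a b-sweep table.

    Estimated as the midpoint between the largest surviving grid point
    (mean F_C > threshold) and the first extinct one above it; the grid
    resolution at that point is reported alongside.  Returns None when the
    sweep never crosses the threshold.
    """
    t = table.sort_values("b").reset_index(drop=True)
    alive = t["fc_mean"] > threshold
    if alive.all() or not alive.any():
        return None
    last_alive = int(np.max(np.nonzero(alive.to_numpy())[0]))
    if last_alive + 1 >= len(t):
        return None
    b_lo = float(t["b"][last_alive])
    b_hi = float(t["b"][last_alive + 1])
    return {"b_c": 0.5 * (b_lo + b_hi), "resolution": b_hi - b_lo}
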