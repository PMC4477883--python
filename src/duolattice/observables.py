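"""Measured quantities: cooperator fractions, partner-pair fractions,
stationary tail averages, and cooperator-cluster statistics.

The headline observable is the stationary fraction of cooperators F_C,
averaged over the two layers and over a tail window of the Monte Carlo
trajectory.  Partner pairs are classified by the strategies of co-located
players on the two layers: CC (both cooperate), DD (both defect) and CD
(mixed, pooling both orientations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .model_core import COOPERATOR, DuplexState

__all__ = [
    "TimeSeries",
    "StationaryStats",
    "ClusterStats",
    "cooperator_fraction",
    "pair_fractions",
    "pair_counts",
    "stationary_average",
    "cluster_stats",
]


@dataclass
class TimeSeries:
    """Per-MCS record of layer cooperation fractions and pair fractions.

    Index 0 is the initial configuration; index t is the state after t full
    Monte Carlo steps.
    """

    mcs: np.ndarray
    fc_upper: np.ndarray
    fc_lower: np.ndarray
    f_cc: np.ndarray
    f_cd: np.ndarray
    f_dd: np.ndarray

    @property
    def fc_mean(self) -> np.ndarray:
        return 0.5 * (self.fc_upper + self.fc_lower)

    def __len__(self) -> int:
        return len(self.mcs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mcs": self.mcs,
                "Fc_upper": self.fc_upper,
                "Fc_lower": self.fc_lower,
                "Fc_mean": self.fc_mean,
                "f_CC": self.f_cc,
                "f_CD": self.f_cd,
                "f_DD": self.f_dd,
            }
        )

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            mcs=df["mcs"].to_numpy(),
            fc_upper=df["Fc_upper"].to_numpy(),
            fc_lower=df["Fc_lower"].to_numpy(),
            f_cc=df["f_CC"].to_numpy(),
            f_cd=df["f_CD"].to_numpy(),
            f_dd=df["f_DD"].to_numpy(),
        )


@dataclass(frozen=True)
class StationaryStats:
    """Tail-window means of every recorded observable."""

    fc_upper: float
    fc_lower: float
    fc_mean: float
    f_cc: float
    f_cd: float
    f_dd: float


def cooperator_fraction(grid: np.ndarray) -> float:
    """Fraction of cooperators on one layer: (# C) / L^2."""
    return float(np.count_nonzero(grid == COOPERATOR) / grid.size)


def pair_counts(upper: np.ndarray, lower: np.ndarray) -> Tuple[int, int, int, int]:
    """Oriented partner-pair counts (cc, cd, dc, dd).

    ``cd`` counts pairs whose upper member cooperates while the lower
    defects; ``dc`` the reverse orientation.  Retained internally so that
    f_CC + (upper-C share of mixed pairs) can be checked against Fc_upper.
    """
    uc = upper == COOPERATOR
    lc = lower == COOPERATOR
    cc = int(np.count_nonzero(uc & lc))
    cd = int(np.count_nonzero(uc & ~lc))
    dc = int(np.count_nonzero(~uc & lc))
    dd = int(np.count_nonzero(~uc & ~lc))
    return cc, cd, dc, dd


def pair_fractions(
    state: Union[DuplexState, Tuple[np.ndarray, np.ndarray]]
) -> Tuple[float, float, float]:
    """(f_CC, f_CD, f_DD) over all L^2 cross-layer partner pairs.

    CD pools both orientations; the three fractions sum to 1 exactly.
    """
    if isinstance(state, DuplexState):
        upper, lower = state.upper, state.lower
    else:
        upper, lower = state
    cc, cd, dc, dd = pair_counts(upper, lower)
    n = upper.size
    return cc / n, (cd + dc) / n, dd / n


def stationary_average(series: TimeSeries, window: int) -> StationaryStats:
    """Arithmetic mean of each observable over the final ``window`` records."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series):
        raise ValueError(
            f"window {window} exceeds series length {len(series)}"
        )
    sl = slice(len(series) - window, len(series))
    return StationaryStats(
        fc_upper=float(series.fc_upper[sl].mean()),
        fc_lower=float(series.fc_lower[sl].mean()),
        fc_mean=float(series.fc_mean[sl].mean()),
        f_cc=float(series.f_cc[sl].mean()),
        f_cd=float(series.f_cd[sl].mean()),
        f_dd=float(series.f_dd[sl].mean()),
    )


@dataclass(frozen=True)
class ClusterStats:
    """Connected same-strategy components under periodic 4-adjacency."""

    sizes: Tuple[int, ...]  # sorted descending
    largest_fraction: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def to_histogram(self) -> pd.DataFrame:
        sizes, counts = np.unique(np.array(self.sizes, dtype=int), return_counts=True)
        return pd.DataFrame({"cluster_size": sizes, "count": counts})


def cluster_stats(grid: np.ndarray, strategy: int = COOPERATOR) -> ClusterStats:
    """Cluster sizes of one strategy under the dynamics' own topology.

    Components are labelled with 4-connectivity and then merged across the
    periodic seams, so a cluster wrapping the boundary counts once.
    """
    mask = grid == strategy
    labels, n = ndimage.label(mask)
    if n == 0:
        return ClusterStats(sizes=(), largest_fraction=0.0)

    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # merge across the two periodic seams
    for a, b in zip(labels[0, :], labels[-1, :]):
        if a and b:
            union(a, b)
    for a, b in zip(labels[:, 0], labels[:, -1]):
        if a and b:
            union(a, b)

    raw_sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    merged: dict[int, int] = {}
    for lab in range(1, n + 1):
        root = find(lab)
        merged[root] = merged.get(root, 0) + int(raw_sizes[lab - 1])
    sizes = tuple(sorted(merged.values(), reverse=True))
    return ClusterStats(sizes=sizes, largest_fraction=sizes[0] / grid.size)
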