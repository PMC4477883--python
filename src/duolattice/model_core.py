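"""Game definition, lattice geometry, strategy grids and initial conditions.

The game is the weak prisoner's dilemma parameterized by the temptation
``b``: a defector exploiting a cooperator earns ``T = b > 1``, mutual
cooperation pays ``R = 1``, and both the punishment ``P`` and the sucker's
payoff ``S`` are 0.  Players occupy the sites of two ``L x L`` square
lattices (the *upper* and *lower* layer of a duplex); each player interacts
with its four von Neumann neighbors under periodic boundary conditions and
is tied to the co-located partner on the other layer through a per-site
coupling strength (see :mod:`duolattice.coupling`).

Strategies are stored as ``int8`` arrays with 1 = cooperator, 0 = defector.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "COOPERATOR",
    "DEFECTOR",
    "PayoffParams",
    "LatticeGeometry",
    "DuplexState",
    "neighbor_table",
    "accumulated_payoff",
    "random_init",
    "patch_init",
    "grid_to_text",
    "grid_from_text",
]

COOPERATOR: int = 1
DEFECTOR: int = 0

PatchLayers = Literal["both", "upper-only", "lower-only"]


@dataclass(frozen=True)
class PayoffParams:
    """Payoff matrix of the weak prisoner's dilemma plus the Fermi noise.

    Parameters
    ----------
    b:
        Temptation to defect ``T``.  The ranking ``T > R > P >= S`` requires
        ``1 < b <= 2``; construction enforces it unless ``allow_unranked``
        is set (exploratory runs outside the dilemma region).
    K:
        Selection noise of the Fermi adoption rule, must be positive.
    """

    b: float
    K: float = 0.1
    R: float = 1.0
    P: float = 0.0
    S: float = 0.0
    allow_unranked: bool = False

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"noise K must be positive, got {self.K}")
        if not self.allow_unranked and not (1.0 < self.b <= 2.0):
            raise ValueError(
                f"temptation b={self.b} violates the payoff ranking "
                "T > R > P >= S (need 1 < b <= 2); pass allow_unranked=True "
                "to override for exploratory runs"
            )

    def matrix(self) -> np.ndarray:
        """Row-player payoff matrix ``M[s_x, s_y]`` indexed D=0, C=1."""
        return np.array(
            [[self.P, self.b], [self.S, self.R]], dtype=np.float64
        )


@dataclass(frozen=True)
class LatticeGeometry:
    """Square ``L x L`` lattice, von Neumann neighborhood, periodic boundary."""

    L: int

    def __post_init__(self) -> None:
        if self.L < 4 or self.L % 2 != 0:
            raise ValueError(f"lattice side L must be even and >= 4, got {self.L}")

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    def neighbors(self) -> np.ndarray:
        """``(L*L, 4)`` int32 table of flat neighbor indices (N, S, W, E)."""
        return neighbor_table(self.L)


@lru_cache(maxsize=32)
def neighbor_table(L: int) -> np.ndarray:
    """Flat-index von Neumann neighbor table with periodic wrapping."""
    idx = np.arange(L * L, dtype=np.int64).reshape(L, L)
    nbr = np.stack(
        [
            np.roll(idx, 1, axis=0),   # north
            np.roll(idx, -1, axis=0),  # south
            np.roll(idx, 1, axis=1),   # west
            np.roll(idx, -1, axis=1),  # east
        ],
        axis=-1,
    ).reshape(L * L, 4)
    nbr = np.ascontiguousarray(nbr, dtype=np.int32)
    nbr.setflags(write=False)
    return nbr


@dataclass
class DuplexState:
    """Two strategy grids, their coupling field, geometry and payoffs.

    The partner map is the identity on coordinates: the partner of site
    ``(i, j)`` on one layer is ``(i, j)`` on the other.
    """

    upper: np.ndarray
    lower: np.ndarray
    coupling: "object"  # CouplingField; kept untyped to avoid an import cycle
    geometry: LatticeGeometry
    payoff: PayoffParams

    def __post_init__(self) -> None:
        L = self.geometry.L
        for name, grid in (("upper", self.upper), ("lower", self.lower)):
            if grid.shape != (L, L):
                raise ValueError(f"{name} grid shape {grid.shape} != ({L}, {L})")
            vals = np.unique(grid)
            if not np.all(np.isin(vals, (DEFECTOR, COOPERATOR))):
                raise ValueError(f"{name} grid holds values other than C/D")

    def grid(self, layer: str) -> np.ndarray:
        if layer == "upper":
            return self.upper
        if layer == "lower":
            return self.lower
        raise ValueError(f"unknown layer {layer!r}")

    def partner_grid(self, layer: str) -> np.ndarray:
        return self.lower if layer == "upper" else self.grid("upper") if layer == "lower" else self.grid(layer)

    def copy(self) -> "DuplexState":
        return DuplexState(
            upper=self.upper.copy(),
            lower=self.lower.copy(),
            coupling=self.coupling,
            geometry=self.geometry,
            payoff=self.payoff,
        )


def accumulated_payoff(state: DuplexState, layer: str, site: Tuple[int, int]) -> float:
    """Payoff of the player at ``site`` summed over its 4 neighbors.

    Pure query: does not mutate the state.  Raises ``IndexError`` for an
    out-of-range coordinate.
    """
    L = state.geometry.L
    i, j = site
    if not (0 <= i < L and 0 <= j < L):
        raise IndexError(f"site {site} outside a {L}x{L} grid")
    grid = state.grid(layer)
    m = state.payoff.matrix()
    s = grid[i, j]
    total = 0.0
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        total += m[s, grid[(i + di) % L, (j + dj) % L]]
    return float(total)


def random_init(
    geometry: LatticeGeometry, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Independent C/D assignment with probability 1/2 per site per layer."""
    L = geometry.L
    upper = rng.integers(0, 2, size=(L, L), dtype=np.int8)
    lower = rng.integers(0, 2, size=(L, L), dtype=np.int8)
    return upper, lower


def patch_init(
    geometry: LatticeGeometry,
    patch_side: int,
    layers: PatchLayers = "both",
) -> Tuple[np.ndarray, np.ndarray]:
    """All-defector layers with a centered square cooperator patch.

    The patch of side ``patch_side`` starts at offset
    ``(L - patch_side) // 2`` on both axes of the selected layer(s); the
    unselected layer is entirely defectors.
    """
    L = geometry.L
    if patch_side > L:
        raise ValueError(f"patch_side {patch_side} exceeds lattice side {L}")
    if patch_side < 1:
        raise ValueError("patch_side must be >= 1")
    if layers not in ("both", "upper-only", "lower-only"):
        raise ValueError(f"unknown patch layers {layers!r}")
    off = (L - patch_side) // 2
    sl = slice(off, off + patch_side)
    upper = np.zeros((L, L), dtype=np.int8)
    lower = np.zeros((L, L), dtype=np.int8)
    if layers in ("both", "upper-only"):
        upper[sl, sl] = COOPERATOR
    if layers in ("both", "lower-only"):
        lower[sl, sl] = COOPERATOR
    return upper, lower


# ---------------------------------------------------------------------------
# plain-text serialization: header line "L", then one row of C/D per line


def grid_to_text(grid: np.ndarray) -> str:
    L = grid.shape[0]
    lines = [str(L)]
    for row in grid:
        lines.append("".join("C" if v == COOPERATOR else "D" for v in row))
    return "\n".join(lines) + "\n"


def grid_from_text(text: str) -> np.ndarray:
    buf = io.StringIO(text)
    L = int(buf.readline())
    rows = []
    for _ in range(L):
        line = buf.readline().strip()
        if len(line) != L or set(line) - {"C", "D"}:
            raise ValueError("malformed strategy-grid text")
        rows.append([COOPERATOR if c == "C" else DEFECTOR for c in line])
    return np.array(rows, dtype=np.int8)
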