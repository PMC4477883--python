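"""Asynchronous Monte Carlo dynamics: utilities, Fermi adoption, elementary
steps, full Monte Carlo steps, and whole simulation runs.

The update rule is pairwise comparison (Fermi rule): a randomly chosen
focal player x picks one of its four same-layer neighbors y uniformly and
adopts s_y with probability ``W = 1 / (1 + exp((U_x - U_y) / K))``, where
``U = pi + alpha * pi_partner`` mixes a player's own accumulated payoff
with its cross-layer partner's payoff through the player's own coupling
entry.  Strategies never cross layers — only payoff information does.

One full Monte Carlo step (MCS) consists of ``2 L^2`` elementary steps
(random sequential with replacement over the union of both layers), so
every player of both lattices receives one update opportunity on average.

``run_simulation`` drives the JIT-compiled kernel for whole trajectories;
``elementary_step`` / ``full_mcs`` are the reference python path used for
small lattices and oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Tuple

import numpy as np

from . import _kernel
from .coupling import DISORDERS, SCHEMES, CouplingField, draw_coupling_field, refresh_if_annealed
from .model_core import (
    DuplexState,
    LatticeGeometry,
    PayoffParams,
    patch_init,
    random_init,
)
from .observables import TimeSeries

__all__ = [
    "SimConfig",
    "StepOutcome",
    "utility",
    "fermi_prob",
    "elementary_step",
    "full_mcs",
    "run_simulation",
    "initialize_state",
]

# exponent clamp: beyond |z| = 700, exp overflows float64 and W is exactly 0/1
_CLAMP = 700.0


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run.

    Defaults follow the study conditions: K = 0.1, mcs_total = 5e4 with the
    stationary average taken over the last 1e4 full MCS.
    """

    L: int = 200
    b: float = 1.05
    K: float = 0.1
    A: float = 0.5
    scheme: str = "symmetric"
    disorder: str = "quenched"
    init: str = "random"          # "random" | "patch"
    patch_side: int = 40
    patch_layers: str = "both"    # "both" | "upper-only" | "lower-only"
    mcs_total: int = 50_000
    mcs_measure: int = 10_000
    seed: int = 0
    early_stop: bool = True
    allow_unranked_b: bool = False

    def __post_init__(self) -> None:
        LatticeGeometry(self.L)  # validates L
        PayoffParams(self.b, K=self.K, allow_unranked=self.allow_unranked_b)
        if not (0.0 <= self.A <= 1.0):
            raise ValueError(f"amplitude A must lie in [0, 1], got {self.A}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown coupling scheme {self.scheme!r}")
        if self.disorder not in DISORDERS:
            raise ValueError(f"unknown disorder {self.disorder!r}")
        if self.init not in ("random", "patch"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.init == "patch" and self.patch_layers not in (
            "both",
            "upper-only",
            "lower-only",
        ):
            raise ValueError(f"unknown patch_layers {self.patch_layers!r}")
        if self.mcs_total < 1 or self.mcs_measure < 1:
            raise ValueError("mcs_total and mcs_measure must be >= 1")
        if self.mcs_measure > self.mcs_total:
            raise ValueError("mcs_measure cannot exceed mcs_total")

    @property
    def geometry(self) -> LatticeGeometry:
        return LatticeGeometry(self.L)

    @property
    def payoff(self) -> PayoffParams:
        return PayoffParams(self.b, K=self.K, allow_unranked=self.allow_unranked_b)

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StepOutcome:
    """Record of one elementary step."""

    layer: str
    site: Tuple[int, int]
    neighbor: Tuple[int, int]
    probability: float
    adopted: bool


def utility(state: DuplexState, layer: str, site: Tuple[int, int]) -> float:
    """``U_x = pi_x + alpha_x * pi_x'`` with payoffs taken fresh from the grids.

    ``alpha_x`` is the focal player's own coupling entry in its own layer;
    the partner x' is the co-located player on the other layer.
    """
    from .model_core import accumulated_payoff

    other = "lower" if layer == "upper" else "upper"
    alpha = (
        state.coupling.alpha_upper if layer == "upper" else state.coupling.alpha_lower
    )
    pi_x = accumulated_payoff(state, layer, site)
    pi_partner = accumulated_payoff(state, other, site)
    return pi_x + float(alpha[site]) * pi_partner


def fermi_prob(u_x: float, u_y: float, K: float) -> float:
    """Probability that x adopts y's strategy: ``1 / (1 + exp((U_x - U_y)/K))``.

    Overflow-safe for arbitrarily large utility gaps (exponent clamped at
    +-700, where the probability is exactly 0/1 in float64).
    """
    if K <= 0:
        raise ValueError(f"noise K must be positive, got {K}")
    z = (u_x - u_y) / K
    if z > _CLAMP:
        return 0.0
    if z < -_CLAMP:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def elementary_step(state: DuplexState, rng: np.random.Generator) -> StepOutcome:
    """One asynchronous update attempt; mutates at most one site.

    The focal player is uniform over all ``2 L^2`` players of both layers;
    the model neighbor is uniform over its 4 same-layer neighbors.  Both
    utilities carry their own coupling terms.
    """
    L = state.geometry.L
    n = L * L
    r = int(rng.integers(0, 2 * n))
    layer = "upper" if r < n else "lower"
    idx = r % n
    site = (idx // L, idx % L)
    di, dj = ((-1, 0), (1, 0), (0, -1), (0, 1))[int(rng.integers(0, 4))]
    nbr = ((site[0] + di) % L, (site[1] + dj) % L)

    grid = state.grid(layer)
    u_x = utility(state, layer, site)
    u_y = utility(state, layer, nbr)
    p = fermi_prob(u_x, u_y, state.payoff.K)
    adopted = bool(rng.random() < p)
    if adopted:
        grid[site] = grid[nbr]
    return StepOutcome(layer=layer, site=site, neighbor=nbr, probability=p, adopted=adopted)


def full_mcs(state: DuplexState, rng: np.random.Generator) -> DuplexState:
    """One full MCS: exactly ``2 L^2`` elementary steps (with replacement).

    Redraws the coupling field first when the disorder is annealed.
    Reference python implementation; the kernel path in
    :func:`run_simulation` is the production loop.
    """
    state.coupling = refresh_if_annealed(state.coupling, rng)
    for _ in range(2 * state.geometry.n_sites):
        elementary_step(state, rng)
    return state


def initialize_state(config: SimConfig, rng: np.random.Generator) -> DuplexState:
    """Build the initial duplex (grids + coupling field) from a config."""
    geometry = config.geometry
    if config.init == "random":
        upper, lower = random_init(geometry, rng)
    else:
        upper, lower = patch_init(geometry, config.patch_side, config.patch_layers)
    field_ = draw_coupling_field(
        geometry, config.A, config.scheme, rng, disorder=config.disorder
    )
    return DuplexState(
        upper=upper,
        lower=lower,
        coupling=field_,
        geometry=geometry,
        payoff=config.payoff,
    )


def run_simulation(
    config: SimConfig,
) -> Tuple[TimeSeries, DuplexState]:
    """Run a full trajectory; returns the per-MCS series and the final state.

    Everything is seeded from ``config.seed``: the initial grids, the
    coupling field, and the kernel's update stream.  Identical configs give
    bit-identical trajectories.  With ``early_stop`` (default), stepping
    halts once both layers are homogeneous (all-C or all-D is absorbing)
    and the remaining records are filled with the constant value.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_state(config, rng)
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    n_mcs = config.mcs_total
    fc_u = np.empty(n_mcs + 1)
    fc_l = np.empty(n_mcs + 1)
    f_cc = np.empty(n_mcs + 1)
    f_dd = np.empty(n_mcs + 1)

    N = config.L * config.L
    # pack both layers flat, upper first; partner of i is i +- N
    s = np.concatenate(
        [state.upper.reshape(-1), state.lower.reshape(-1)]
    ).astype(np.int8)
    a = np.concatenate(
        [state.coupling.alpha_upper.reshape(-1), state.coupling.alpha_lower.reshape(-1)]
    ).astype(np.float64)
    nbr1 = config.geometry.neighbors()
    nbr = np.vstack([nbr1, nbr1 + np.int32(N)])

    su, sl = s[:N], s[N:]
    fc_u[0] = su.sum() / N
    fc_l[0] = sl.sum() / N
    f_cc[0] = np.count_nonzero((su == 1) & (sl == 1)) / N
    f_dd[0] = np.count_nonzero((su == 0) & (sl == 0)) / N

    annealed = config.disorder == "annealed" and config.scheme != "homogeneous"
    _kernel.run_kernel(
        s,
        a,
        nbr,
        config.payoff.matrix(),
        config.K,
        n_mcs,
        kernel_seed,
        config.early_stop,
        annealed,
        config.scheme == "symmetric",
        config.A,
        fc_u,
        fc_l,
        f_cc,
        f_dd,
    )

    L = config.L
    final = DuplexState(
        upper=s[:N].reshape(L, L),
        lower=s[N:].reshape(L, L),
        coupling=CouplingField(
            a[:N].reshape(L, L),
            a[N:].reshape(L, L),
            config.A,
            config.scheme,
            config.disorder,
        ),
        geometry=config.geometry,
        payoff=config.payoff,
    )
    series = TimeSeries(
        mcs=np.arange(n_mcs + 1),
        fc_upper=fc_u,
        fc_lower=fc_l,
        f_cc=f_cc,
        f_cd=1.0 - f_cc - f_dd,
        f_dd=f_dd,
    )
    return series, final
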