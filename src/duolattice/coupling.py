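"""Heterogeneous cross-layer coupling fields.

Each player's utility mixes its own payoff with its partner's payoff,
``U_x = pi_x + alpha_x * pi_x'``.  The per-player coupling strength is
``alpha = A * chi`` with ``chi ~ Uniform(-1, 1)``, so ``alpha`` lies in
``[-A, A]`` and averages to zero.  Two heterogeneous assignment schemes are
supported:

* ``symmetric`` (case I): one draw per site *pair* — corresponding partners
  on the two layers share the same alpha, exactly.
* ``asymmetric`` (case II): every player on every layer draws independently.

A ``homogeneous`` baseline (alpha identically ``A >= 0`` everywhere)
recovers the constant-coupling convention of earlier interdependent-lattice
models.  ``A = 0`` decouples the layers in every scheme, recovering two
independent standard lattices.

The disorder is *quenched* by default: the field is drawn once at
initialization and held fixed.  An *annealed* variant redraws it once per
Monte Carlo step via :func:`refresh_if_annealed`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import LatticeGeometry

__all__ = ["CouplingField", "draw_coupling_field", "refresh_if_annealed"]

SCHEMES = ("symmetric", "asymmetric", "homogeneous")
DISORDERS = ("quenched", "annealed")


@dataclass
class CouplingField:
    """Per-site coupling strengths for both layers of the duplex."""

    alpha_upper: np.ndarray
    alpha_lower: np.ndarray
    amplitude: float
    scheme: str
    disorder: str = "quenched"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown coupling scheme {self.scheme!r}")
        if self.disorder not in DISORDERS:
            raise ValueError(f"unknown disorder {self.disorder!r}")
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError(f"amplitude A must lie in [0, 1], got {self.amplitude}")
        if self.alpha_upper.shape != self.alpha_lower.shape:
            raise ValueError("layer fields differ in shape")
        A = self.amplitude
        for arr in (self.alpha_upper, self.alpha_lower):
            if self.scheme == "homogeneous":
                if not np.all(arr == A):
                    raise ValueError("homogeneous field must equal A everywhere")
            elif arr.size and (arr.min() < -A or arr.max() > A):
                raise ValueError("coupling entries outside [-A, A]")
        if self.scheme == "symmetric" and not np.array_equal(
            self.alpha_upper, self.alpha_lower
        ):
            raise ValueError("symmetric scheme requires identical layer fields")


def draw_coupling_field(
    geometry: LatticeGeometry,
    A: float,
    scheme: str,
    rng: np.random.Generator,
    disorder: str = "quenched",
) -> CouplingField:
    """Draw a coupling field ``alpha = A * chi``, ``chi ~ U(-1, 1)``.

    Symmetric: one chi per site pair, copied to both layers.  Asymmetric:
    an independent chi per site per layer.  Homogeneous: alpha = A
    everywhere (no randomness).  Deterministic under a fixed generator
    state.
    """
    if not (0.0 <= A <= 1.0):
        raise ValueError(f"amplitude A must lie in [0, 1], got {A}")
    L = geometry.L
    shape = (L, L)
    if scheme == "symmetric":
        alpha = A * rng.uniform(-1.0, 1.0, size=shape)
        upper, lower = alpha, alpha.copy()
    elif scheme == "asymmetric":
        upper = A * rng.uniform(-1.0, 1.0, size=shape)
        lower = A * rng.uniform(-1.0, 1.0, size=shape)
    elif scheme == "homogeneous":
        upper = np.full(shape, A)
        lower = np.full(shape, A)
    else:
        raise ValueError(f"unknown coupling scheme {scheme!r}")
    return CouplingField(upper, lower, A, scheme, disorder)


def refresh_if_annealed(field: CouplingField, rng: np.random.Generator) -> CouplingField:
    """Redraw the field when annealed; return it unchanged when quenched."""
    if field.disorder == "quenched":
        return field
    geometry = LatticeGeometry(field.alpha_upper.shape[0])
    return draw_coupling_field(
        geometry, field.amplitude, field.scheme, rng, disorder="annealed"
    )
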