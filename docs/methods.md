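# Model and methods

## The model

Two square lattices of `L × L` players (the *upper* and *lower* layer of a
duplex) each play the weak prisoner's dilemma with their four von Neumann
neighbors under periodic boundary conditions.  The one-shot game is
parameterized by the temptation `b`: the row player receives

| | opponent C | opponent D |
|---|---|---|
| **C** | R = 1 | S = 0 |
| **D** | T = b | P = 0 |

with `1 < b ≤ 2` so the ranking `T > R > P ≥ S` holds.  A player's
accumulated payoff `π_x` is the sum of the four one-shot payoffs against its
neighbors.

The two layers are interdependent through utility only — strategies never
cross layers.  Each player `x` has a partner `x'` at the same coordinates on
the other layer, and evaluates

```
U_x = π_x + α_x · π_x'
```

where `α_x = A·χ_x` is a quenched per-player coupling strength, with
`χ ~ Uniform(−1, 1)` and amplitude `A ∈ [0, 1]`.  Two assignment schemes are
implemented:

* **symmetric** (case I): one `χ` per site pair; partners share their
  coupling exactly (`α_x = α_x'`).
* **asymmetric** (case II): every player on every layer draws independently.
* **homogeneous** baseline: `α ≡ A ≥ 0` everywhere (the constant-coupling
  convention of earlier interdependent-lattice models).

`A = 0` decouples the layers, each of which then evolves as an ordinary
spatial prisoner's dilemma.

## Dynamics

Asynchronous Monte Carlo with the Fermi (pairwise-comparison) rule.  One
elementary step: draw a focal player uniformly from the union of both
layers (`2L²` players), draw one of its four same-layer neighbors `y`, and
let `x` adopt `s_y` with probability

```
W(s_y → s_x) = 1 / (1 + exp((U_x − U_y) / K))
```

with selection noise `K = 0.1` by default.  Both utilities carry their own
coupling terms and are recomputed from the current grids at every
elementary step — no payoff caching.  One full Monte Carlo step (MCS) is
exactly `2L²` elementary steps (random sequential with replacement), so
every player of both lattices is updated once on average.  The exponent of
the Fermi rule is clamped at ±700; beyond that the adoption probability is
exactly 0 or 1 in double precision.

The JIT-compiled kernel skips the utility evaluation when the focal player
and its chosen neighbor already share a strategy: adopting an identical
strategy cannot change the state, so the trajectory distribution is
unchanged while the loop runs several times faster.  The pure-python
`elementary_step`/`full_mcs` path computes the full adoption record and is
the oracle the kernel is checked against.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `L` | 200 | lattice side (sites); both layers share it |
| `b` | 1.05 | temptation to defect, dimensionless, `1 < b ≤ 2` |
| `K` | 0.1 | Fermi selection noise |
| `A` | 0.5 | coupling amplitude, half-width of `[−A, A]` |
| `scheme` | symmetric | coupling assignment (see above) |
| `disorder` | quenched | coupling fixed per run; `annealed` redraws each MCS |
| `mcs_total` | 5×10⁴ | trajectory length in full MCS |
| `mcs_measure` | 10⁴ | tail window for stationary averages |
| `early_stop` | on | stop stepping once both layers are homogeneous |

Early stopping is exact, not an approximation: all-C and all-D duplexes
are absorbing, so the remaining records are filled with the constant value.

Quenched disorder is the default because the coupling reads most naturally
as a fixed per-player trait: only a persistent coupling lets favorably
coupled cooperator pairs consolidate into durable seeds, whereas a
per-step redraw reduces the coupling term to zero-mean utility noise.  The
annealed switch exists for sensitivity analysis.

## Observables

* `F_C` per layer: cooperator count / `L²`; the headline quantity is the
  two-layer mean, averaged over the last `mcs_measure` records.
* Pair fractions over the `L²` partner pairs: `f_CC` (both cooperate),
  `f_DD` (both defect), `f_CD` (mixed, pooling both orientations — the
  oriented counts are kept internally so `f_CC` + upper-C-mixed share can be
  checked against `F_C` of the upper layer).
* Cooperator clusters: connected components under the same periodic
  4-adjacency the dynamics uses, merged across the lattice seams; the
  "giant component" is reported as the continuous largest-cluster fraction.

## Experiment drivers and replicate protocol

Sweeps over `b` or `A` run `replicates` independent realizations per grid
point, replicate `r` seeded as `base_seed + r`, each with fresh initial
grids and a fresh coupling field.  Rows report the replicate mean of the
stationary `F_C`, its standard error, per-layer means and the mean `f_CC`.
Cooperation counts as extinct when the stationary mean `F_C ≤ 0.005`; the
extinction temptation `b_c` is estimated as the midpoint between the last
surviving and the first extinct grid point, reported with the local grid
resolution.

Patch experiments start from a centered `patch_side × patch_side`
cooperator block (offset `⌊(L − side)/2⌋` on both axes) on one or both
layers, all other players defecting, and return a persisted/extinct
verdict.

## Problem sizes

Production defaults are `L = 200`, 5×10⁴ MCS and up to 20 replicates.  The
test suite and the acceptance script run at desk scale — `L = 100` (200 for
the patch experiments), 5×10³–10⁴ MCS with 1–2×10³-step tail windows and
5–10 replicates — which reproduces every qualitative result (the optimum at
`A = 0.5` under case I, full defection at `A = 0`, the patch logic, the
monotone `b` response) with run times of minutes.

Scheme ordering at near-saturation is the one delicate comparison: at
`b = 1.05`, `A = 0.5` both schemes converge to `F_C ≈ 0.99` and differ by
only a few tenths of a percent, comparable to the replicate standard error
of 10 desk-scale realizations.  The suite compares them one-sidedly at two
pooled standard errors; at `A = 0.5` that comparison sits at its own
tolerance boundary (the asymmetric scheme can come out marginally ahead at
this lattice size and window), while at `A = 1.0`, where both schemes hold
visible defector populations, the symmetric scheme's advantage is
reproducible.  A definitive ranking at saturation would need
production-scale lattices and windows.

## Numerical choices

* Strategies are `int8` (1 = C, 0 = D); payoffs come from a 2×2 float
  matrix, so non-default `R`, `P`, `S` values remain possible internally.
* RNG: `numpy` PCG64 seeds the initial grids and coupling field; the kernel
  uses numba's internal generator seeded from the same stream, so a run is
  a pure function of its config.
* Degenerate inputs: `b` outside `(1, 2]` is a validation error unless an
  explicit override flag is set (validation, never silent clamping);
  `A` outside `[0, 1]`, odd or tiny `L`, oversized patches and
  over-long measurement windows all raise with the offending field named.
* Ties: equal utilities give adoption probability exactly 1/2.

## What the simulations do and do not show

All inputs are synthetic by construction (the model *is* the study object;
there is no external data).  Desk-scale lattices have larger finite-size
fluctuations than `L = 200–400`, so threshold locations (`b_c`, `A_c`)
carry grid- and size-resolution error, and the `L`-dependence of results is
not validated here.  Cluster statistics are reported descriptively; no
percolation-threshold claim is made.  Alternative interdependence
mechanisms (strategy transfer, biased or co-evolving coupling,
lattice–network interconnection) are out of scope.
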