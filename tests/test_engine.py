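"""Fermi rule, elementary steps, full MCS, whole runs, and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from duolattice import (
    COOPERATOR,
    DEFECTOR,
    SimConfig,
    elementary_step,
    fermi_prob,
    full_mcs,
    run_simulation,
    utility,
)
from duolattice.model_core import accumulated_payoff

from conftest import make_state, random_state

finite_utils = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


class TestFermiProb:
    def test_equal_utilities(self):
        assert fermi_prob(3.3, 3.3, 0.1) == 0.5

    def test_closed_form_unit_gap(self):
        # delta-U/K = 1 -> 1/(1+e)
        assert fermi_prob(0.1, 0.0, 0.1) == pytest.approx(1 / (1 + math.e), abs=1e-12)

    def test_saturation(self):
        assert fermi_prob(-10.0, 0.0, 0.1) == pytest.approx(1.0, abs=1e-43)
        assert fermi_prob(1e6, 0.0, 0.1) == 0.0  # overflow-safe

    def test_invalid_noise(self):
        with pytest.raises(ValueError):
            fermi_prob(0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(u_x=finite_utils, u_y=finite_utils, K=st.floats(min_value=1e-3, max_value=10))
    def test_complementarity(self, u_x, u_y, K):
        assert fermi_prob(u_x, u_y, K) + fermi_prob(u_y, u_x, K) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_strictly_decreasing_in_gap(self):
        # |z| <= 30 keeps 1 + exp(z) away from float saturation
        gaps = np.linspace(-3, 3, 101)
        probs = [fermi_prob(g, 0.0, 0.1) for g in gaps]
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestUtility:
    def test_direct_substitution(self):
        # interior cooperator among cooperators: pi = 4 on both layers
        state = make_state(np.ones((4, 4)), np.ones((4, 4)), A=0.5)
        alpha = state.coupling.alpha_upper[1, 1]
        assert utility(state, "upper", (1, 1)) == pytest.approx(4 + alpha * 4)

    def test_zero_coupling_reduces_to_own_payoff(self, rng):
        state = random_state(6, rng, A=0.0)
        for site in [(0, 0), (3, 2), (5, 5)]:
            assert utility(state, "upper", site) == accumulated_payoff(
                state, "upper", site
            )

    def test_negative_coupling(self):
        # upper all-C (pi = 4), lower all-C; force alpha = -1 everywhere
        state = make_state(np.ones((4, 4)), np.ones((4, 4)), A=0.0)
        state.coupling.alpha_upper[:] = -1.0
        state.coupling.alpha_lower[:] = -1.0
        assert utility(state, "upper", (2, 2)) == pytest.approx(4 - 4)

    @pytest.mark.parametrize("L", [4, 8])
    def test_oracle_recomputation(self, L, rng):
        """Engine utilities equal payoff + alpha * partner payoff, exactly."""
        state = random_state(L, rng, A=1.0, scheme="asymmetric")
        for layer, alpha in (
            ("upper", state.coupling.alpha_upper),
            ("lower", state.coupling.alpha_lower),
        ):
            other = "lower" if layer == "upper" else "upper"
            for i in range(L):
                for j in range(L):
                    expected = accumulated_payoff(state, layer, (i, j)) + alpha[
                        i, j
                    ] * accumulated_payoff(state, other, (i, j))
                    assert utility(state, layer, (i, j)) == expected


class TestElementarySteps:
    def test_all_defector_state_is_absorbing(self, rng):
        state = make_state(np.zeros((4, 4)), np.zeros((4, 4)))
        for _ in range(200):
            elementary_step(state, rng)
        assert not state.upper.any() and not state.lower.any()

    def test_mutates_at_most_one_site(self, rng):
        state = random_state(6, rng)
        before_u, before_l = state.upper.copy(), state.lower.copy()
        out = elementary_step(state, rng)
        changed = np.count_nonzero(before_u != state.upper) + np.count_nonzero(
            before_l != state.lower
        )
        assert changed <= 1
        assert 0.0 <= out.probability <= 1.0

    def test_focal_selection_uniform(self):
        """Chi-square goodness of fit of focal (layer, site) frequencies."""
        rng = np.random.default_rng(77)
        state = random_state(4, rng)
        counts = np.zeros((2, 16))
        n_steps = 64_000
        for _ in range(n_steps):
            out = elementary_step(state, rng)
            layer = 0 if out.layer == "upper" else 1
            counts[layer, out.site[0] * 4 + out.site[1]] += 1
        _, p = stats.chisquare(counts.ravel())
        assert p > 0.01


class TestFullMcs:
    def test_all_cooperator_state_unchanged(self, rng):
        state = make_state(np.ones((4, 4)), np.ones((4, 4)), A=1.0)
        for _ in range(3):
            full_mcs(state, rng)
        assert state.upper.all() and state.lower.all()

    def test_deterministic_under_seed(self):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            state = random_state(6, rng, b=1.2)
            full_mcs(state, rng)
            runs.append((state.upper.copy(), state.lower.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestRunSimulation:
    def test_bit_identical_repeat(self):
        cfg = SimConfig(L=16, mcs_total=300, mcs_measure=50, seed=4)
        s1, f1 = run_simulation(cfg)
        s2, f2 = run_simulation(cfg)
        assert np.array_equal(s1.fc_upper, s2.fc_upper)
        assert np.array_equal(s1.f_cc, s2.f_cc)
        assert np.array_equal(f1.upper, f2.upper)
        assert np.array_equal(f1.lower, f2.lower)

    @pytest.mark.parametrize(
        "A,scheme,b", [(0.0, "symmetric", 1.05), (1.0, "asymmetric", 1.6), (0.5, "homogeneous", 1.2)]
    )
    def test_all_cooperator_state_absorbing(self, A, scheme, b):
        """An all-C duplex never moves, for any coupling setup."""
        cfg = SimConfig(
            L=8, A=A, scheme=scheme, b=b, init="patch", patch_side=8,
            patch_layers="both", mcs_total=1000, mcs_measure=10, seed=1,
            early_stop=False,
        )
        series, final = run_simulation(cfg)
        assert np.all(series.fc_upper == 1.0) and np.all(series.fc_lower == 1.0)
        assert final.upper.all() and final.lower.all()

    def test_all_defector_absorbing_via_kernel(self):
        # reach all-D quickly (A=0, high b), then confirm it never leaves
        cfg = SimConfig(L=8, A=0.0, b=2.0, mcs_total=2000, mcs_measure=10, seed=3,
                        early_stop=False)
        series, final = run_simulation(cfg)
        assert series.fc_mean[-1] == 0.0
        extinct_at = int(np.argmax((series.fc_upper + series.fc_lower) == 0))
        assert np.all(series.fc_upper[extinct_at:] == 0.0)

    def test_pair_fraction_conservation_each_mcs(self):
        cfg = SimConfig(L=16, A=1.0, scheme="asymmetric", mcs_total=200,
                        mcs_measure=50, seed=8)
        series, _ = run_simulation(cfg)
        total = series.f_cc + series.f_cd + series.f_dd
        assert np.all(np.abs(total - 1.0) < 1e-12)
        assert np.all(series.f_cc <= np.minimum(series.fc_upper, series.fc_lower) + 1e-12)
        assert np.allclose(series.fc_mean, 0.5 * (series.fc_upper + series.fc_lower))

    def test_early_stop_fills_constant_tail(self):
        cfg = SimConfig(L=8, A=0.0, b=2.0, mcs_total=5000, mcs_measure=100, seed=3,
                        early_stop=True)
        series, _ = run_simulation(cfg)
        assert series.fc_mean[-1] == 0.0
        assert len(series) == 5001

    def test_annealed_run_executes(self):
        cfg = SimConfig(L=8, A=0.5, disorder="annealed", mcs_total=50,
                        mcs_measure=10, seed=2)
        series, final = run_simulation(cfg)
        assert len(series) == 51
        assert np.abs(final.coupling.alpha_upper).max() <= 0.5


def _single_lattice_reference(L, b, K, n_mcs, seed):
    """Independent single-lattice Fermi-update simulator (oracle for A=0).

    Deliberately coded from scratch: 2D grid, python RNG calls, no shared
    machinery with the production kernel beyond numpy.
    """
    rng = np.random.default_rng(seed)
    grid = rng.integers(0, 2, size=(L, L), dtype=np.int8)
    payoff = {(1, 1): 1.0, (1, 0): 0.0, (0, 1): b, (0, 0): 0.0}

    def pi(i, j):
        s = grid[i, j]
        return sum(
            payoff[(s, grid[(i + di) % L, (j + dj) % L])]
            for di, dj in [(-1, 0), (1, 0), (0, -1), (0, 1)]
        )

    fc = np.empty(n_mcs)
    for t in range(n_mcs):
        for _ in range(L * L):
            i, j = rng.integers(0, L, size=2)
            di, dj = [(-1, 0), (1, 0), (0, -1), (0, 1)][rng.integers(0, 4)]
            ni, nj = (i + di) % L, (j + dj) % L
            if grid[i, j] == grid[ni, nj]:
                continue  # adopting an identical strategy is a no-op
            w = 1.0 / (1.0 + np.exp(np.clip((pi(i, j) - pi(ni, nj)) / K, -700, 700)))
            if rng.random() < w:
                grid[i, j] = grid[ni, nj]
        fc[t] = grid.mean()
    return fc


def test_decoupled_layers_match_single_lattice_reference():
    """At A=0 each layer evolves as an independent standard spatial game.

    Distributional check at desk scale: stationary F_C of the duplex layers
    against an independently coded single-lattice simulator, at a temptation
    where cooperation survives on a single lattice.
    """
    L, b, n_mcs, tail = 24, 1.02, 250, 50
    ref = [
        _single_lattice_reference(L, b, 0.1, n_mcs, seed=100 + r)[-tail:].mean()
        for r in range(4)
    ]
    dup = []
    for r in range(4):
        cfg = SimConfig(L=L, A=0.0, b=b, mcs_total=n_mcs, mcs_measure=tail,
                        seed=200 + r, early_stop=False)
        series, _ = run_simulation(cfg)
        dup.append(series.fc_upper[-tail:].mean())
        dup.append(series.fc_lower[-tail:].mean())
    ref_m, dup_m = np.mean(ref), np.mean(dup)
    se = np.sqrt(np.var(ref, ddof=1) / len(ref) + np.var(dup, ddof=1) / len(dup))
    assert abs(ref_m - dup_m) < 4 * se + 0.02
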