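"""Backward-induction solvers: oracles, invariants, discretisation."""

import numpy as np
import pytest

from immunoalloc import (
    DeterministicGain,
    ModelParams,
    ReserveGrid,
    StochasticGain,
    closed_form_optimum,
    solve_deterministic,
    solve_stochastic,
    transition,
)
from immunoalloc.core import survival_current, survival_future


class TestTransition:
    def test_arithmetic(self):
        assert transition(1.0, 0.6, 0.4, 0.5) == pytest.approx(0.5)

    def test_cap_at_r_max(self):
        assert transition(1.0, 0.0, 0.0, 0.5) == 1.0

    def test_full_depletion(self):
        assert transition(0.3, 0.3, 0.0, 0.0) == 0.0

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            transition(0.5, 0.4, 0.2, 0.1)
        with pytest.raises(ValueError):
            transition(1.0, -0.1, 0.0, 0.1)


class TestGrid:
    def test_grid_spans_unit_interval(self):
        g = ReserveGrid(11)
        assert g.values[0] == 0.0 and g.values[-1] == 1.0
        assert np.all(np.diff(g.values) > 0)

    def test_nearest_index(self):
        g = ReserveGrid(11)
        assert g.nearest_index(0.0) == 0
        assert g.nearest_index(0.26) == 3
        assert g.nearest_index(1.2) == 10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ReserveGrid(1)


def _enumeration_oracle(params, grid, gains, probs, T):
    """Plain-python brute-force value iteration, independent of the solver."""
    v = list(grid.values)
    n = len(v)

    def interp(x, w):
        x = min(max(x, 0.0), 1.0)
        for a in range(n - 1):
            if v[a] <= x <= v[a + 1]:
                lam = (x - v[a]) / (v[a + 1] - v[a])
                return (1 - lam) * w[a] + lam * w[a + 1]
        return w[-1]

    W = [[0.0] * n for _ in range(T)]
    for t in range(T - 1, 0, -1):
        for k in range(n):
            total = 0.0
            for g, p in zip(gains, probs):
                best = -1.0
                for i in range(k + 1):
                    for j in range(k - i + 1):
                        val = (
                            float(params.phi_max * v[j] ** params.alpha)
                            * float(survival_current(v[i], params))
                            + float(survival_future(v[i], params))
                            * interp(v[k] - v[i] - v[j] + g, W[t])
                        )
                        best = max(best, val)
                total += p * best
            W[t - 1][k] = total
    return np.asarray(W)


class TestDeterministicSolver:
    def test_terminal_value_is_zero(self, small_grid):
        pol = solve_deterministic(ModelParams(), small_grid, DeterministicGain.exponential(), T=5)
        assert np.all(pol.W[-1] == 0.0)

    def test_value_monotone_in_reserves_and_nonnegative(self, small_grid):
        pol = solve_deterministic(
            ModelParams(M=1.5, gamma=3.0, f=0.7), small_grid, DeterministicGain.exponential(), T=8
        )
        assert np.all(pol.W >= 0.0)
        assert np.all(np.diff(pol.W, axis=1) >= -1e-9)

    def test_policy_feasible_everywhere(self, small_grid):
        pol = solve_deterministic(ModelParams(M=2.0, gamma=5.0), small_grid,
                                  DeterministicGain.exponential(), T=8)
        tot = pol.r_i_star + pol.r_o_star
        assert np.all(tot <= small_grid.values[None, :] + small_grid.step + 1e-12)

    def test_last_decision_period_reduces_to_semelparous(self, rng):
        # with W(., T) = 0 the final decision is the single-season problem
        grid = ReserveGrid(101)
        gain = DeterministicGain.constant(0.5)
        for _ in range(20):
            M = rng.uniform(0.3, 3.0)
            g = rng.uniform(0.5, 8.0)
            f = rng.uniform(0.1, 1.0)
            if M * f * g / 0.5 < 1.1:
                continue
            p = ModelParams(M=M, gamma=g, f=f)
            pol = solve_deterministic(p, grid, gain, T=3)
            cf = closed_form_optimum(1.0, p)
            assert abs(pol.r_i_star[-1, -1] - cf.r_i_star) <= grid.step + 1e-12

    def test_longer_brooding_invests_more(self):
        grid = ReserveGrid(51)
        gain = DeterministicGain.exponential()
        ri = {}
        for f in (0.1, 0.9):
            p = ModelParams(M=1.0, gamma=5.0, f=f)
            pol = solve_deterministic(p, grid, gain, T=20)
            ri[f] = pol.policy_at(1.0, t=1)[0]
        assert ri[0.9] >= ri[0.1]

    def test_grid_refinement_stability(self):
        p = ModelParams(M=1.0, gamma=4.0, f=0.5)
        gain = DeterministicGain.exponential()
        w = {}
        for n in (51, 201):
            pol = solve_deterministic(p, grid=ReserveGrid(n), gain=gain, T=10)
            w[n] = pol.value_at(1.0, 1)
        assert abs(w[201] - w[51]) / w[201] < 0.01

    def test_horizon_too_short_rejected(self, small_grid):
        with pytest.raises(ValueError):
            solve_deterministic(ModelParams(), small_grid, DeterministicGain.exponential(), T=1)


class TestStochasticSolver:
    def test_degenerate_support_matches_deterministic_exactly(self, small_grid):
        p = ModelParams(M=1.0, gamma=4.0, f=0.5)
        det = solve_deterministic(p, small_grid, DeterministicGain.constant(0.5), T=10)
        sto = solve_stochastic(p, small_grid, StochasticGain.degenerate(0.5), T=10)
        np.testing.assert_array_equal(det.W, sto.W)
        np.testing.assert_array_equal(det.r_i_star, sto.r_i_star[:, :, 0])
        np.testing.assert_array_equal(det.r_o_star, sto.r_o_star[:, :, 0])

    def test_value_is_convex_combination_of_per_gain_maxima(self, small_grid):
        p = ModelParams(M=1.0, gamma=4.0, f=0.5)
        gains = [0.2, 0.7]
        probs = [0.4, 0.6]
        gm = StochasticGain(support=np.array(gains), probs=np.array(probs))
        sto = solve_stochastic(p, small_grid, gm, T=6)
        per_gain = [
            solve_deterministic(p, small_grid, DeterministicGain.constant(g), T=6).W
            for g in gains
        ]
        lo = np.minimum(*per_gain)
        hi = np.maximum(*per_gain)
        # mixing over gain levels every period keeps W within the envelope
        # of the two constant-gain solutions at the final decision period
        assert np.all(sto.W[-2] >= lo[-2] - 1e-9)
        assert np.all(sto.W[-2] <= hi[-2] + 1e-9)

    def test_matches_exhaustive_enumeration_oracle(self):
        grid = ReserveGrid(5)
        p = ModelParams(M=1.0, gamma=3.0, f=0.6)
        gains = [0.2, 0.7]
        probs = [0.4, 0.6]
        gm = StochasticGain(support=np.array(gains), probs=np.array(probs))
        pol = solve_stochastic(p, grid, gm, T=3)
        oracle = _enumeration_oracle(p, grid, gains, probs, T=3)
        np.testing.assert_allclose(pol.W, oracle, rtol=0, atol=1e-10)

    def test_value_monotone_and_zero_at_horizon(self, small_policy):
        assert np.all(small_policy.W[-1] == 0.0)
        assert np.all(np.diff(small_policy.W, axis=1) >= -1e-9)

    def test_policy_feasible_per_gain_level(self, small_policy, small_grid):
        tot = small_policy.r_i_star + small_policy.r_o_star
        cap = small_grid.values[None, :, None] + small_grid.step + 1e-12
        assert np.all(tot <= cap)

    def test_long_format_export_columns(self, small_policy):
        df = small_policy.to_frame()
        assert list(df.columns) == ["t", "r", "gain_level", "gain", "W", "r_i_star", "r_o_star"]
        n_rows = (small_policy.horizon_T - 1) * small_policy.grid.n_points * small_policy.gain.n_levels
        assert len(df) == n_rows

    def test_policy_lookup_requires_gain_index(self, small_policy):
        with pytest.raises(ValueError):
            small_policy.policy_at(0.5, t=1)
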