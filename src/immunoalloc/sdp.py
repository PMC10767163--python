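"""Backward-induction solvers for the iteroparous allocation problem.

The state is (reserves r, period t). Reproductive senescence occurs at the
horizon T, so the terminal value is W(r, T) = 0 for all r. For earlier
periods, backward induction computes

    W(r, t) = max_{r_i, r_o}  Phi(r_o) * S_current(r_i)
              + S_future(r_i) * W(r - r_i - r_o + g, t + 1),

where g is the deterministic gain g(t), or, in the stochastic variant, the
expectation over the discrete-Gaussian gain levels g_n of the per-level
maxima (the parent observes the period's gain before allocating, so the
policy is indexed by gain level as well as state).

Reserves live on a uniform grid on [0, 1] and allocations are restricted
to grid multiples, so r - r_i - r_o falls exactly on the grid and only the
added gain requires interpolation of the continuation value (linear, which
preserves monotonicity of W in r). Post-gain reserves are capped at
r_max = 1; excess gain is wasted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gain import DeterministicGain, StochasticGain
from .params import ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "ReserveGrid",
    "PolicySolution",
    "transition",
    "solve_deterministic",
    "solve_stochastic",
    "constant_policy",
]


@dataclass(frozen=True)
class ReserveGrid:
    """Uniform discretisation of the reserve interval [0, r_max = 1]."""

    n_points: int = 101
    values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        object.__setattr__(self, "values", np.linspace(0.0, 1.0, self.n_points))

    @property
    def step(self) -> float:
        return 1.0 / (self.n_points - 1)

    def nearest_index(self, r) -> np.ndarray:
        """Index of the grid point nearest to reserves r (ties round up)."""
        return np.clip(np.rint(np.asarray(r) / self.step).astype(int), 0, self.n_points - 1)


def transition(r: float, r_o: float, r_i: float, gain: float, r_max: float = 1.0) -> float:
    """Next-period reserves r - r_o - r_i + gain, clipped to [0, r_max]."""
    if r_o < 0 or r_i < 0:
        raise ValueError("allocations must be >= 0")
    if r_o + r_i > r + 1e-12:
        raise ValueError(f"infeasible allocation: r_i + r_o = {r_i + r_o} > r = {r}")
    if gain < 0:
        raise ValueError(f"gain must be >= 0, got {gain}")
    return float(np.clip(r - r_o - r_i + gain, 0.0, r_max))


@dataclass
class PolicySolution:
    """Value table W(r, t) and optimal allocation policy.

    For the deterministic solver ``r_i_star``/``r_o_star`` have shape
    (T-1, n); for the stochastic solver (T-1, n, L) with L gain levels —
    the allocation chosen after observing gain level g_n. ``W`` always has
    shape (T, n) with W[T-1] = 0 (terminal senescence).

    Time is 1-based: row ``t - 1`` of each array holds period ``t``.
    """

    grid: ReserveGrid
    horizon_T: int
    W: np.ndarray
    r_i_star: np.ndarray
    r_o_star: np.ndarray
    params: ModelParams
    gain: DeterministicGain | StochasticGain
    stochastic: bool

    def policy_at(self, r: float, t: int, gain_index: int | None = None) -> tuple[float, float]:
        """Optimal (r_i, r_o) at the grid point nearest reserves r, period t."""
        if not 1 <= t <= self.horizon_T - 1:
            raise ValueError(f"t must lie in [1, T-1], got {t}")
        k = self.grid.nearest_index(r)
        if self.stochastic:
            if gain_index is None:
                raise ValueError("stochastic policy lookup needs a gain_index")
            return float(self.r_i_star[t - 1, k, gain_index]), float(self.r_o_star[t - 1, k, gain_index])
        return float(self.r_i_star[t - 1, k]), float(self.r_o_star[t - 1, k])

    def value_at(self, r: float, t: int) -> float:
        if not 1 <= t <= self.horizon_T:
            raise ValueError(f"t must lie in [1, T], got {t}")
        return float(np.interp(r, self.grid.values, self.W[t - 1]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (t, r, [gain_level, gain,] W, r_i_star, r_o_star)."""
        v = self.grid.values
        rows = []
        for t in range(1, self.horizon_T):
            if self.stochastic:
                for lev, g in enumerate(self.gain.support):
                    for k, r in enumerate(v):
                        rows.append(
                            (t, r, lev, g, self.W[t - 1, k],
                             self.r_i_star[t - 1, k, lev], self.r_o_star[t - 1, k, lev])
                        )
            else:
                for k, r in enumerate(v):
                    rows.append((t, r, self.W[t - 1, k], self.r_i_star[t - 1, k], self.r_o_star[t - 1, k]))
        if self.stochastic:
            cols = ["t", "r", "gain_level", "gain", "W", "r_i_star", "r_o_star"]
        else:
            cols = ["t", "r", "W", "r_i_star", "r_o_star"]
        return pd.DataFrame(rows, columns=cols)


class _Workspace:
    """Precomputed tables for the vectorised allocation search.

    Index convention: i = immune-allocation grid index, j = offspring
    index, k = reserve index; feasibility on a uniform grid is i + j <= k
    and the banked remainder is exactly grid point k - i - j.
    """

    def __init__(self, grid: ReserveGrid, params: ModelParams):
        v = grid.values
        n = v.size
        self.v, self.n = v, n
        phi = params.phi_max * np.power(v, params.alpha)
        scur = np.exp(-params.M * params.f / (1.0 + params.gamma * v))
        self.sfut = np.exp(-params.M / (1.0 + params.gamma * v))
        self.payoff = phi[None, :] * scur[:, None]  # [i, j]
        k = np.arange(n)
        ii, jj = np.meshgrid(k, k, indexing="ij")
        spent = (ii + jj)[None, :, :]
        kk = k[:, None, None]
        self.feasible = spent <= kk
        self.left_idx = np.clip(kk - spent, 0, n - 1).astype(np.int32)

    def best_allocation(self, gain: float, w_next: np.ndarray):
        """Maximise over the feasible allocation triangle for every reserve level.

        Exact ties resolve to the smallest r_i, then the smallest r_o
        (prefer not investing when indifferent).
        """
        w_gain = np.interp(np.clip(self.v + gain, 0.0, 1.0), self.v, w_next)
        val = self.payoff[None, :, :] + self.sfut[None, :, None] * w_gain[self.left_idx]
        val = np.where(self.feasible, val, -np.inf)
        flat = val.reshape(self.n, -1)
        arg = np.argmax(flat, axis=1)  # first max: i-major order = smallest r_i, r_o
        best = flat[np.arange(self.n), arg]
        i, j = np.divmod(arg, self.n)
        return best, self.v[i], self.v[j]


def _validate_solver_args(grid: ReserveGrid, T: int) -> None:
    if T < 2:
        raise ValueError(f"horizon T must be >= 2, got {T}")
    if not isinstance(grid, ReserveGrid):
        raise TypeError("grid must be a ReserveGrid")


def solve_deterministic(
    params: ModelParams,
    grid: ReserveGrid,
    gain: DeterministicGain,
    T: int,
) -> PolicySolution:
    """Backward induction with a known gain schedule g(t)."""
    _validate_solver_args(grid, T)
    if not isinstance(gain, DeterministicGain):
        raise TypeError("deterministic solver needs a DeterministicGain")
    ws = _Workspace(grid, params)
    n = grid.n_points
    W = np.zeros((T, n))
    r_i = np.zeros((T - 1, n))
    r_o = np.zeros((T - 1, n))
    for t in range(T - 1, 0, -1):
        g = gain(t)
        W[t - 1], r_i[t - 1], r_o[t - 1] = ws.best_allocation(g, W[t])
    if np.any(r_i[:, -1] == grid.values[-1]):
        logger.debug("optimal r_i hits the allocation-grid boundary; consider refining the grid")
    return PolicySolution(grid, T, W, r_i, r_o, params, gain, stochastic=False)


def solve_stochastic(
    params: ModelParams,
    grid: ReserveGrid,
    gain: StochasticGain,
    T: int,
) -> PolicySolution:
    """Backward induction with gain observed before allocating each period.

    W(r, t) is the probability-weighted average over gain levels of the
    per-level maxima; the stored policy is conditional on the observed level.
    """
    _validate_solver_args(grid, T)
    if not isinstance(gain, StochasticGain):
        raise TypeError("stochastic solver needs a StochasticGain")
    ws = _Workspace(grid, params)
    n = grid.n_points
    L = gain.n_levels
    W = np.zeros((T, n))
    r_i = np.zeros((T - 1, n, L))
    r_o = np.zeros((T - 1, n, L))
    for t in range(T - 1, 0, -1):
        acc = np.zeros(n)
        for lev in range(L):
            best, vi, vj = ws.best_allocation(float(gain.support[lev]), W[t])
            acc += gain.probs[lev] * best
            r_i[t - 1, :, lev] = vi
            r_o[t - 1, :, lev] = vj
        W[t - 1] = acc
    return PolicySolution(grid, T, W, r_i, r_o, params, gain, stochastic=True)


def constant_policy(
    params: ModelParams,
    grid: ReserveGrid,
    gain: StochasticGain,
    T: int,
    r_i: float = 0.0,
    r_o: float = 0.0,
) -> PolicySolution:
    """A pinned (non-optimised) policy allocating fixed amounts each period.

    Useful as an experimental control, e.g. r_i = 0 everywhere to recover
    pure background mortality in forward simulation. Allocations are
    truncated where reserves cannot cover them (r_i has priority).
    """
    _validate_solver_args(grid, T)
    v = grid.values
    ri_cell = np.minimum(r_i, v)
    ro_cell = np.minimum(r_o, v - ri_cell)
    L = gain.n_levels
    shape = (T - 1, grid.n_points, L)
    return PolicySolution(
        grid,
        T,
        np.zeros((T, grid.n_points)),
        np.broadcast_to(ri_cell[None, :, None], shape).copy(),
        np.broadcast_to(ro_cell[None, :, None], shape).copy(),
        params,
        gain,
        stochastic=True,
    )
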