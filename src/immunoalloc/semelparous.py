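"""Single-season (semelparous) optimum: closed form, brute force, sweeps.

A semelparous parent breeds once, so its lifetime fitness is the current
reproductive payoff with all reserves spent, r_o = r - r_i:

    W(r_i) = phi_max * (r - r_i)**alpha * exp(-M*f / (1 + gamma*r_i)).

Setting dW/dr_i = 0 yields a quadratic in r_i whose positive branch is

    r_i* = [-(2 + k) + sqrt((2 + k)**2 - 4*(1 - r*k*gamma))] / (2*gamma),

with k = M*f/alpha. A finite, non-negative interior optimum exists iff
r*M*f*gamma/alpha >= 1; below that threshold the fitness is decreasing in
r_i at 0, so the constrained maximiser is the boundary r_i* = 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "SemelparousSolution",
    "semelparous_fitness",
    "closed_form_optimum",
    "feasibility_threshold_gamma",
    "brute_force_optimum",
    "optimum_surface",
]


@dataclass(frozen=True)
class SemelparousSolution:
    """Optimal single-season immune allocation.

    Attributes
    ----------
    r_i_star : float
        Optimal immune allocation, in [0, r].
    interior : bool
        True when the optimum is the interior quadratic root; False when it
        is the boundary r_i = 0 (feasibility condition violated).
    k : float
        The composite ratio M*f/alpha driving the closed form.
    clipped : bool
        True when the unconstrained interior root exceeded r and was clipped.
    """

    r_i_star: float
    interior: bool
    k: float
    clipped: bool = False


def semelparous_fitness(r_i, r: float, params: ModelParams):
    """Single-season fitness W(r_i) = Phi(r - r_i) * S_current(r_i)."""
    r_i = np.asarray(r_i, dtype=float)
    if not np.all(np.isfinite(r_i)):
        raise ValueError("r_i must be finite")
    if np.any(r_i < 0) or np.any(r_i > r + 1e-12):
        raise ValueError(f"r_i must lie in [0, r] with r={r}")
    if not 0 < r <= params.r_max:
        raise ValueError(f"r must lie in (0, r_max], got {r}")
    r_o = np.clip(r - r_i, 0.0, None)
    out = params.phi_max * np.power(r_o, params.alpha) * np.exp(
        -params.M * params.f / (1.0 + params.gamma * r_i)
    )
    return out if out.ndim else float(out)


def closed_form_optimum(r: float, params: ModelParams) -> SemelparousSolution:
    """Closed-form semelparous optimum r_i*.

    Returns the positive branch of the optimality quadratic when the
    feasibility condition r*M*f*gamma/alpha >= 1 holds, clipped to [0, r];
    otherwise the boundary solution r_i* = 0. With gamma = 0 immune
    investment cannot affect survival, so the boundary answer is returned.
    """
    if not 0 < r <= params.r_max:
        raise ValueError(f"r must lie in (0, r_max], got {r}")
    k = params.M * params.f / params.alpha
    if params.gamma == 0.0:
        return SemelparousSolution(0.0, interior=False, k=k)
    feas = r * k * params.gamma  # r*M*f*gamma/alpha
    if feas < 1.0:
        return SemelparousSolution(0.0, interior=False, k=k)
    disc = (2.0 + k) ** 2 - 4.0 * (1.0 - r * k * params.gamma)
    root = (-(2.0 + k) + math.sqrt(disc)) / (2.0 * params.gamma)
    clipped = root > r
    r_i = min(max(root, 0.0), r)
    return SemelparousSolution(r_i, interior=True, k=k, clipped=clipped)


def feasibility_threshold_gamma(r: float, M: float, f: float, alpha: float) -> float:
    """Minimal gamma for a non-negative interior optimum: alpha/(r*M*f).

    Returns ``inf`` when any of r, M, f is zero — no finite efficacy can
    then make immune investment worthwhile.
    """
    for name, v in (("r", r), ("M", M), ("f", f), ("alpha", alpha)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if r == 0 or M == 0 or f == 0:
        return math.inf
    return alpha / (r * M * f)


def brute_force_optimum(r: float, params: ModelParams, n_grid: int = 100_001) -> SemelparousSolution:
    """Grid-search maximiser of the single-season fitness.

    Independent check on :func:`closed_form_optimum`; agreement is within
    one grid spacing ``r / (n_grid - 1)``.
    """
    if n_grid < 100:
        raise ValueError(f"n_grid must be >= 100, got {n_grid}")
    grid = np.linspace(0.0, r, n_grid)
    w = semelparous_fitness(grid, r, params)
    best = int(np.argmax(w))
    r_i = float(grid[best])
    k = params.M * params.f / params.alpha
    return SemelparousSolution(r_i, interior=r_i > 0.0, k=k)


def optimum_surface(
    f_values,
    M_values,
    gamma_values,
    r: float = 1.0,
    alpha: float = 0.5,
    phi_max: float = 100.0,
) -> pd.DataFrame:
    """Closed-form optimum over a (f, M, gamma) parameter grid.

    One row per combination with columns
    ``(f, M, gamma, r, alpha, r_i_star, interior)``. Rows with
    ``interior=False`` violate the feasibility condition — there the
    boundary r_i* = 0 is reported, mirroring parameter combinations for
    which no interior solution exists.
    """
    f_values, M_values, gamma_values = map(np.atleast_1d, (f_values, M_values, gamma_values))
    rows = []
    for f, M, g in itertools.product(f_values, M_values, gamma_values):
        p = ModelParams(M=float(M), gamma=float(g), f=float(f), alpha=alpha, phi_max=phi_max)
        sol = closed_form_optimum(r, p)
        rows.append((f, M, g, r, alpha, sol.r_i_star, sol.interior))
    return pd.DataFrame(
        rows, columns=["f", "M", "gamma", "r", "alpha", "r_i_star", "interior"]
    )
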