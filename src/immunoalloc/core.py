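"""Primitive fitness components.

Offspring production is a concave power law of the reserves allocated to
reproduction, Phi(r_o) = phi_max * r_o**alpha. Parental survival over the
brooding fraction ``f`` of the current period is
S_current(r_i) = exp(-M*f / (1 + gamma*r_i)), and survival to the next
breeding season is S_future(r_i) = exp(-M / (1 + gamma*r_i)). Offspring
are credited only if the brooding parent survives the current period, so
the per-period reproductive payoff is Phi(r_o) * S_current(r_i).

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

from .params import Allocation, ModelParams

__all__ = [
    "offspring_count",
    "survival_current",
    "survival_future",
    "current_reproductive_success",
]


def _check_fraction(x, name: str, upper: float | None = None):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    if upper is not None and np.any(arr > upper + 1e-12):
        raise ValueError(f"{name} must be <= {upper}")
    return arr


def offspring_count(r_o, params: ModelParams):
    """Expected offspring produced from allocation ``r_o``.

    Strictly increasing and concave in ``r_o``; ``r_o = 0`` yields exactly 0
    (the continuous limit of ``r_o**alpha`` as ``r_o -> 0+``).
    """
    r_o = _check_fraction(r_o, "r_o", upper=params.r_max)
    out = params.phi_max * np.power(r_o, params.alpha)
    return out if out.ndim else float(out)


def survival_current(r_i, params: ModelParams):
    """Probability the parent survives the brooding fraction of this period."""
    r_i = _check_fraction(r_i, "r_i")
    out = np.exp(-params.M * params.f / (1.0 + params.gamma * r_i))
    return out if out.ndim else float(out)


def survival_future(r_i, params: ModelParams):
    """Probability the parent survives to the next breeding season.

    Identical to :func:`survival_current` at ``f = 1``.
    """
    r_i = _check_fraction(r_i, "r_i")
    out = np.exp(-params.M / (1.0 + params.gamma * r_i))
    return out if out.ndim else float(out)


def current_reproductive_success(alloc: Allocation, params: ModelParams):
    """Expected surviving-brood offspring, Phi(r_o) * S_current(r_i)."""
    return offspring_count(alloc.r_o, params) * survival_current(alloc.r_i, params)
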