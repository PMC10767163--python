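"""Reserve-gain models between breeding periods.

Two flavours are supported:

* deterministic: gain is a known function of time g(t), by default the
  exponential form a + b*exp(-c*t) with (a, b, c) = (0.32, 4, 0.5);
* stochastic: gain is drawn each period from a discrete Gaussian on an
  evenly spaced support g_n = g_min + (n/N)*(g_max - g_min), n = 0..N, with

      p(g_n) = exp(-(g_n - g_bar)^2 / (2 sigma^2)) / normaliser.

The stochastic model represents fluctuating food availability between
seasons; sigma summarises environmental variability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DeterministicGain",
    "StochasticGain",
    "deterministic_gain",
    "build_discrete_gaussian",
]


def deterministic_gain(t, coeffs: tuple[float, float, float] = (0.32, 4.0, 0.5)):
    """Evaluate the default exponential gain form a + b*exp(-c*t) at t >= 1.

    Negative results are clipped to 0 with a warning: gains are resources.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("breeding-period index t must be >= 1")
    a, b, c = coeffs
    g = a + b * np.exp(-c * t)
    if np.any(g < 0):
        logger.warning("negative gain clipped to 0 (coeffs=%s)", coeffs)
        g = np.clip(g, 0.0, None)
    return g if g.ndim else float(g)


@dataclass(frozen=True)
class DeterministicGain:
    """Known gain schedule g(t); ``fn`` maps a period index t >= 1 to a gain."""

    fn: Callable[[int], float]

    @classmethod
    def exponential(cls, a: float = 0.32, b: float = 4.0, c: float = 0.5) -> "DeterministicGain":
        return cls(fn=lambda t, _c=(a, b, c): deterministic_gain(t, _c))

    @classmethod
    def constant(cls, g: float) -> "DeterministicGain":
        if g < 0:
            raise ValueError(f"gain must be >= 0, got {g}")
        return cls(fn=lambda t, _g=g: _g)

    @classmethod
    def saturating(cls, a: float = 0.32, b: float = 4.0, c: float = 0.5) -> "DeterministicGain":
        """Variant a + b*exp(-c/t): rises with t toward the asymptote a + b."""
        return cls(fn=lambda t, _c=(a, b, c): _c[0] + _c[1] * math.exp(-_c[2] / t))

    def __call__(self, t: int) -> float:
        g = float(self.fn(t))
        if g < 0:
            logger.warning("negative gain %.4g at t=%d clipped to 0", g, t)
            g = 0.0
        return g


@dataclass(frozen=True)
class StochasticGain:
    """Discrete Gaussian gain distribution on an evenly spaced support."""

    support: np.ndarray = field(repr=False)
    probs: np.ndarray = field(repr=False)
    g_bar: float = 0.5
    sigma: float = 0.4

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if s.shape != p.shape or s.ndim != 1 or s.size < 1:
            raise ValueError("support and probs must be matching 1-D arrays")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be non-negative and sum to 1")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "probs", p)

    @property
    def n_levels(self) -> int:
        return self.support.size

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probs)

    def draw_indices(self, rho: np.ndarray) -> np.ndarray:
        """Map uniforms in [0, 1) to gain-level indices via the inverse CDF."""
        return np.searchsorted(self.cdf(), rho, side="right").clip(0, self.n_levels - 1)

    @classmethod
    def degenerate(cls, g: float) -> "StochasticGain":
        """Single-point support: the sigma -> 0 limit at gain g."""
        return cls(support=np.array([g]), probs=np.array([1.0]), g_bar=g, sigma=0.0)


def build_discrete_gaussian(
    g_min: float = 0.0,
    g_max: float = 1.0,
    N: int = 20,
    g_bar: float = 0.5,
    sigma: float = 0.4,
) -> StochasticGain:
    """Discrete Gaussian gain model with N+1 evenly spaced levels.

    g_bar and sigma are the *approximate* mean and standard deviation: the
    discretisation and truncation to [g_min, g_max] shift the realised
    moments slightly unless sigma is small relative to the range.
    """
    if not g_min < g_max:
        raise ValueError(f"need g_min < g_max, got {g_min} >= {g_max}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    n = np.arange(N + 1)
    support = g_min + (n / N) * (g_max - g_min)
    w = np.exp(-((support - g_bar) ** 2) / (2.0 * sigma**2))
    probs = w / w.sum()
    return StochasticGain(support=support, probs=probs, g_bar=g_bar, sigma=sigma)
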