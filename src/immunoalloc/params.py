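"""Biological parameter containers and validation.

The model describes a parent that, at the start of each breeding period,
splits its reserves ``r`` between its own immune defence (``r_i``) and
offspring production (``r_o``). All parameters are validated once at
construction; the hot numerical routines assume validated inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Biological constants of the allocation model.

    Parameters
    ----------
    M : float
        Background mortality rate per breeding period (>= 0). Without any
        immune investment, per-period survival is ``exp(-M)``.
    gamma : float
        Efficacy of immune investment (>= 0): survival exponents are divided
        by ``1 + gamma * r_i``. High gamma means a small investment buys a
        large survival gain.
    f : float
        Fraction of the breeding period spent in pregnancy/brooding, in
        [0, 1]. Offspring survive the current period only if the caring
        parent survives that fraction of it.
    alpha : float
        Concavity shape of offspring production, in (0, 1).
    phi_max : float
        Offspring number at full allocation ``r_o = 1`` (> 0).
    r_max : float
        Maximum reserve level; fixed at 1.0 by convention.
    """

    M: float = 1.0
    gamma: float = 2.0
    f: float = 0.5
    alpha: float = 0.5
    phi_max: float = 100.0
    r_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("M", "gamma", "f", "alpha", "phi_max", "r_max"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if self.M < 0:
            raise ValueError(f"M must be >= 0, got {self.M}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in the open interval (0, 1), got {self.alpha}")
        if self.phi_max <= 0:
            raise ValueError(f"phi_max must be > 0, got {self.phi_max}")
        if self.r_max != 1.0:
            raise ValueError(f"r_max is fixed at 1.0 by convention, got {self.r_max}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Allocation:
    """A split of reserves into immune investment and offspring production.

    ``r_i + r_o`` may be strictly less than the available reserves ``r``;
    the remainder is banked and carried into the next period.
    """

    r_i: float
    r_o: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r_i) and math.isfinite(self.r_o)):
            raise ValueError("allocations must be finite")
        if self.r_i < 0 or self.r_o < 0:
            raise ValueError(f"allocations must be >= 0, got r_i={self.r_i}, r_o={self.r_o}")

    @property
    def total(self) -> float:
        return self.r_i + self.r_o

    def feasible_for(self, r: float, tol: float = 1e-12) -> bool:
        """Whether this allocation can be paid out of reserves ``r``."""
        return self.total <= r + tol
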