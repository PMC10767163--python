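"""Experiment configuration: parsing, defaults, bounds checking.

A configuration is a flat mapping (YAML/JSON file or CLI flags) covering
the biological parameters, gain model, solver discretisation, and run
bookkeeping. Unknown keys are rejected so typos fail loudly; every run
writes back the fully resolved configuration for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gain import DeterministicGain, StochasticGain, build_discrete_gaussian
from .params import ModelParams

__all__ = ["ExperimentConfig", "validate_config", "load_config"]

_EXPERIMENTS = {
    "semelparous-sweep",
    "sdp-policy",
    "forward-sim",
    "emergent-mortality",
    "table2",
}


@dataclass
class ExperimentConfig:
    """Typed, bounds-checked experiment configuration."""

    experiment: str = "sdp-policy"
    # biological parameters
    M: float = 1.0
    gamma: float = 2.0
    f: float = 0.5
    alpha: float = 0.5
    phi_max: float = 100.0
    # gain model
    gain_mode: str = "stochastic"  # or "deterministic"
    gain_a: float = 0.32
    gain_b: float = 4.0
    gain_c: float = 0.5
    g_min: float = 0.0
    g_max: float = 1.0
    N: int = 20
    g_bar: float = 0.5
    sigma: float = 0.4
    # solver / simulation
    grid_points: int = 101
    T: int = 20
    K: int = 200
    seed: int = 0
    # sweep grids
    f_values: list = field(default_factory=lambda: [0.1, 0.5, 0.9])
    M_values: list = field(default_factory=lambda: [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
    gamma_values: list = field(default_factory=lambda: [1.0, 2.0, 4.0, 5.0, 8.0])
    # output
    out_dir: str = "runs"
    plot: bool = False

    def model_params(self, **overrides) -> ModelParams:
        base = dict(M=self.M, gamma=self.gamma, f=self.f, alpha=self.alpha, phi_max=self.phi_max)
        base.update(overrides)
        return ModelParams(**base)

    def gain_model(self) -> DeterministicGain | StochasticGain:
        if self.gain_mode == "deterministic":
            return DeterministicGain.exponential(self.gain_a, self.gain_b, self.gain_c)
        return build_discrete_gaussian(self.g_min, self.g_max, self.N, self.g_bar, self.sigma)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(cond: bool, key: str, constraint: str, value) -> None:
    if not cond:
        raise ValueError(f"config key '{key}' = {value!r} violates constraint: {constraint}")


def validate_config(raw: dict) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a raw mapping.

    Unknown keys raise with the offending key named; out-of-bounds values
    raise with the constraint spelled out.
    """
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
    cfg = ExperimentConfig(**raw)
    _require(cfg.experiment in _EXPERIMENTS, "experiment", f"one of {sorted(_EXPERIMENTS)}", cfg.experiment)
    _require(cfg.M >= 0, "M", "M >= 0", cfg.M)
    _require(cfg.gamma >= 0, "gamma", "gamma >= 0", cfg.gamma)
    _require(0.0 <= cfg.f <= 1.0, "f", "f in [0, 1]", cfg.f)
    _require(0.0 < cfg.alpha < 1.0, "alpha", "alpha in the open interval (0, 1)", cfg.alpha)
    _require(cfg.phi_max > 0, "phi_max", "phi_max > 0", cfg.phi_max)
    _require(cfg.gain_mode in {"deterministic", "stochastic"}, "gain_mode",
             "one of ['deterministic', 'stochastic']", cfg.gain_mode)
    _require(cfg.g_min < cfg.g_max, "g_min", "g_min < g_max", cfg.g_min)
    _require(cfg.N >= 1, "N", "N >= 1", cfg.N)
    _require(cfg.sigma > 0, "sigma", "sigma > 0", cfg.sigma)
    _require(cfg.grid_points >= 2, "grid_points", "grid_points >= 2", cfg.grid_points)
    _require(cfg.T >= 2, "T", "T >= 2", cfg.T)
    _require(cfg.K >= 1, "K", "K >= 1", cfg.K)
    for key in ("f_values", "M_values", "gamma_values"):
        vals = getattr(cfg, key)
        _require(len(vals) > 0, key, "non-empty list", vals)
    _require(all(0.0 <= f <= 1.0 for f in cfg.f_values), "f_values", "all f in [0, 1]", cfg.f_values)
    return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    """Read and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a JSON superset
    return validate_config(raw or {})


def snapshot(cfg: ExperimentConfig, out_dir: str | Path) -> Path:
    """Write the resolved config (+ library version) beside run artifacts."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"config": cfg.to_dict(), "seed": cfg.seed, "immunoalloc_version": __version__}
    path = out / "config.json"
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    return path
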