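"""Run configuration: geometry, fluid properties, fit strategy, seed.

A flat YAML file with strict unknown-key rejection, e.g.::

    geometry:
      h: 7.8e-4        # spacer height, m
      eps: 0.85        # spacer porosity
      S_vp: 1.0e4      # spacer specific surface, 1/m
      L: 0.3           # channel length, m
    solution:
      rho: 997.0       # kg/m^3
      eta: 8.9e-4      # Pa s
      D: 6.0e-11       # m^2/s
      v_r: 0.167       # crossflow velocity, m/s
    model: advection   # or general
    fit_strategy: per_condition   # shared_kdbl | fixed_kdbl
    fixed_kdbl_value: 7.34e-6     # m/s, for fixed_kdbl strategy
    sherwood_correlation: schock_miquel
    seed: 20240126
    output_dir: results
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .masstransfer import CORRELATIONS, ModuleGeometry, SolutionProperties

__all__ = ["RunConfig", "ConfigError", "load_config"]

_STRATEGIES = ("per_condition", "shared_kdbl", "fixed_kdbl")
_MODELS = ("advection", "general")


class ConfigError(ValueError):
    """The configuration file is invalid."""


@dataclass
class RunConfig:
    geometry: Optional[ModuleGeometry] = None
    solution: Optional[SolutionProperties] = None
    model: str = "advection"
    fit_strategy: str = "per_condition"
    fixed_kdbl_value: Optional[float] = None
    sherwood_correlation: Optional[str] = None
    seed: int = 20240126
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ConfigError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.fit_strategy not in _STRATEGIES:
            raise ConfigError(
                f"fit_strategy must be one of {_STRATEGIES}, got {self.fit_strategy!r}"
            )
        if self.sherwood_correlation is not None and \
                self.sherwood_correlation not in CORRELATIONS:
            raise ConfigError(
                f"unknown sherwood_correlation {self.sherwood_correlation!r}"
            )
        if self.fit_strategy == "fixed_kdbl" and self.fixed_kdbl_value is None \
                and self.sherwood_correlation is None:
            raise ConfigError(
                "fixed_kdbl strategy needs fixed_kdbl_value or sherwood_correlation"
            )


_TOP_KEYS = {"geometry", "solution", "model", "fit_strategy", "fixed_kdbl_value",
             "sherwood_correlation", "seed", "output_dir"}
_GEOMETRY_KEYS = {"h", "eps", "S_vp", "L"}
_SOLUTION_KEYS = {"rho", "eta", "D", "v_r"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys are errors)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    geometry = solution = None
    if "geometry" in raw:
        _check_keys(raw["geometry"], _GEOMETRY_KEYS, "geometry")
        geometry = ModuleGeometry(**{k: float(v) for k, v in raw["geometry"].items()})
    if "solution" in raw:
        _check_keys(raw["solution"], _SOLUTION_KEYS, "solution")
        solution = SolutionProperties(**{k: float(v) for k, v in raw["solution"].items()})
    kw = {k: v for k, v in raw.items() if k not in ("geometry", "solution")}
    if "fixed_kdbl_value" in kw and kw["fixed_kdbl_value"] is not None:
        kw["fixed_kdbl_value"] = float(kw["fixed_kdbl_value"])
    if "seed" in kw:
        kw["seed"] = int(kw["seed"])
    return RunConfig(geometry=geometry, solution=solution, **kw)
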