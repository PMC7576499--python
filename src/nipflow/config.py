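"""Run configuration: strict YAML schema for the end-to-end pipeline.

Unknown keys are rejected so that typos fail fast, before any file is
written.  All randomness in a run flows from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .kinetics import CellGeometry, ShockConditions

__all__ = ["StrainConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class StrainConfig:
    name: str
    pf: float  # cm s^-1 at t_ref
    pgly: float  # cm s^-1 at t_ref
    ea_water: float  # kcal mol^-1
    ea_glycerol: float  # kcal mol^-1

    def __post_init__(self):
        if self.pf <= 0:
            raise ConfigError(f"strain {self.name}: pf must be positive")
        if self.pgly < 0:
            raise ConfigError(f"strain {self.name}: pgly must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    strains: tuple[StrainConfig, ...]
    v0_over_a: float = 8.3e-5
    v_w: float = 18.07
    active_fraction: float = 1.0
    osm_in: float = 1.4  # osmol L^-1
    osm_out: float = 2.1
    temperatures: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
    t_ref: float = 23.0
    replicates: int = 3
    noise_sd: float = 0.01
    mode: str = "exponential"
    seed: int = 0
    pore: bool = True
    conservation: bool = True

    def __post_init__(self):
        if self.osm_in <= 0 or self.osm_out <= 0:
            raise ConfigError("osmolarities must be positive")
        if self.osm_out <= self.osm_in:
            raise ConfigError("osm_out must exceed osm_in (hyperosmotic shock)")
        if self.mode not in ("exponential", "ode"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if len(self.strains) == 0:
            raise ConfigError("at least one strain required")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def geometry(self) -> CellGeometry:
        return CellGeometry(
            v0_over_a=self.v0_over_a,
            v_w=self.v_w,
            active_fraction=self.active_fraction,
        )

    def conditions(self, shock_solute: str) -> ShockConditions:
        return ShockConditions(
            osm_in_initial=self.osm_in,
            osm_out_final=self.osm_out,
            shock_solute=shock_solute,
        )


_RUN_KEYS = {
    "v0_over_a", "v_w", "active_fraction", "osm_in", "osm_out",
    "temperatures", "t_ref", "replicates", "noise_sd", "mode", "seed",
    "strains", "pore", "conservation",
}
_STRAIN_KEYS = {"name", "pf", "pgly", "ea_water", "ea_glycerol"}


def _from_mapping(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    raw_strains = data.get("strains", [])
    if not isinstance(raw_strains, list):
        raise ConfigError("strains must be a list")
    strains = []
    for entry in raw_strains:
        if not isinstance(entry, dict):
            raise ConfigError("each strain must be a mapping")
        bad = set(entry) - _STRAIN_KEYS
        if bad:
            raise ConfigError(f"unknown strain keys: {sorted(bad)}")
        missing = _STRAIN_KEYS - set(entry)
        if missing:
            raise ConfigError(f"strain missing keys: {sorted(missing)}")
        strains.append(StrainConfig(**entry))
    kwargs = {k: v for k, v in data.items() if k != "strains"}
    if "temperatures" in kwargs:
        kwargs["temperatures"] = tuple(float(t) for t in kwargs["temperatures"])
    try:
        return RunConfig(strains=tuple(strains), **kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return _from_mapping(data if data is not None else {})
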