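"""Run configuration: schema, defaults and validation.

A run config is a small YAML mapping naming (or spelling out) a geometry
and a material table, plus the sweep grids and numerical settings.  Unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constitutive import HGOLayer
from .geometry import ClosedAnnulus, OpenSector
from .synthetic import fixture

__all__ = ["RunConfig", "ConfigError", "load_config"]

_KNOWN_KEYS = {
    "geometry", "materials", "alphas", "pressures", "out_dir",
    "grid", "seed", "tolerances",
}
_KNOWN_TOLERANCES = {"root", "boundary"}
_DEFAULT_TOLERANCES = {"root": 1e-10, "boundary": 1e-8}


class ConfigError(ValueError):
    """Schema violation in a run config; message lists the offending keys."""


@dataclass
class RunConfig:
    """Validated run configuration with defaults applied."""

    geometry: OpenSector | ClosedAnnulus
    materials: dict[str, HGOLayer]
    alphas: list[float] = field(default_factory=list)
    pressures: list[float] = field(default_factory=list)
    out_dir: Path = Path(".")
    grid: int = 401
    seed: int = 0
    tolerances: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TOLERANCES))


def _build_geometry(spec):
    if isinstance(spec, str):
        fx = fixture(spec)
        geo = fx.sector if fx.sector is not None else fx.annulus
        if geo is None:
            raise ConfigError(f"fixture {spec!r} carries no geometry")
        return geo
    if not isinstance(spec, dict):
        raise ConfigError("geometry must be a fixture name or a mapping")
    if "R_i" in spec:
        return OpenSector(R_i=spec["R_i"], R_m=spec["R_i"] + spec["T_m"],
                          R_o=spec["R_i"] + spec["T_m"] + spec["T_a"],
                          alpha=spec.get("alpha", 0.0))
    if "r_i" in spec:
        return ClosedAnnulus(r_i=spec["r_i"], r_m=spec["r_i"] + spec["t_m"],
                             r_o=spec["r_i"] + spec["t_m"] + spec["t_a"],
                             p_lumen=spec.get("p_lumen", 0.0))
    raise ConfigError("geometry mapping needs R_i/T_m/T_a (sector) or r_i/t_m/t_a (annulus)")


def _build_materials(spec) -> dict[str, HGOLayer]:
    if isinstance(spec, str):
        fx = fixture(spec if spec != "rabbit" else "rabbit_omega0")
        if fx.materials is None:
            raise ConfigError(f"fixture {spec!r} carries no usable material table")
        return fx.materials
    if not isinstance(spec, dict):
        raise ConfigError("materials must be a fixture name or a per-layer mapping")
    return {name: HGOLayer(name=name, **params) for name, params in spec.items()}


def load_config(path) -> RunConfig:
    """Read and validate a YAML run config, applying documented defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for required in ("geometry", "materials"):
        if required not in raw:
            raise ConfigError(f"missing required key: {required!r}")

    tolerances = dict(_DEFAULT_TOLERANCES)
    extra = raw.get("tolerances") or {}
    bad = set(extra) - _KNOWN_TOLERANCES
    if bad:
        raise ConfigError(f"unknown tolerance keys: {sorted(bad)}")
    tolerances.update(extra)
    if any(v <= 0 for v in tolerances.values()):
        raise ConfigError("tolerances must be positive")

    pressures = [float(p) for p in raw.get("pressures", [])]
    if any(p < 0 for p in pressures):
        raise ConfigError("pressures must be non-negative")
    alphas = [float(a) for a in raw.get("alphas", [])]
    if any(not 0 <= a < 360 for a in alphas):
        raise ConfigError("alphas must lie in [0, 360) degrees")
    grid = int(raw.get("grid", 401))
    if grid < 11:
        raise ConfigError(f"grid size must be at least 11, got {grid}")

    return RunConfig(
        geometry=_build_geometry(raw["geometry"]),
        materials=_build_materials(raw["materials"]),
        alphas=alphas,
        pressures=pressures,
        out_dir=Path(raw.get("out_dir", ".")),
        grid=grid,
        seed=int(raw.get("seed", 0)),
        tolerances=tolerances,
    )
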