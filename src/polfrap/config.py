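"""YAML configuration for simulations, grids, noise and scenarios.

One flat YAML file drives all stages; every section is optional and falls
back to the package defaults. Sections: ``model``, ``geometry``,
``acquisition``, ``simulation``, ``noise``, ``grid``, ``fit``, ``preprocess``,
``scenario``.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError
from .fit import ParameterGrid
from .models import (
    AcquisitionConfig,
    GeometryConfig,
    KineticModel,
    NoiseSpec,
    SimulationConfig,
)

__all__ = [
    "load_config",
    "build_model",
    "build_sim_config",
    "build_noise_spec",
    "build_grid",
    "DEFAULT_GRID",
]

#: Default fitting grid; brackets every built-in condition model. Residence
#: times in seconds (t_elong values correspond to 18–32 min).
DEFAULT_GRID = ParameterGrid(
    f_prom=(0.1125, 0.225, 0.45),
    f_elong=(0.25, 0.30, 0.35),
    t_prom=(15.0, 30.0, 60.0),
    t_elong=tuple(60.0 * m for m in (18.0, 20.0, 23.0, 25.0, 28.75, 32.0)),
    seed_offsets=tuple(range(10)),
)


def load_config(path) -> dict:
    """Read a YAML config file into a plain dict (empty file → empty dict)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def build_model(cfg: dict) -> KineticModel:
    section = dict(cfg.get("model", {}))
    if not section:
        raise ConfigError("config has no 'model' section")
    return KineticModel(**section)


def build_sim_config(cfg: dict) -> SimulationConfig:
    geo = GeometryConfig(**{
        k: tuple(v) if k == "semi_axes" else v
        for k, v in dict(cfg.get("geometry", {})).items()
    })
    acq = AcquisitionConfig(**dict(cfg.get("acquisition", {})))
    section = dict(cfg.get("simulation", {}))
    return SimulationConfig(geometry=geo, acquisition=acq, **section)


def build_noise_spec(cfg: dict) -> NoiseSpec:
    return NoiseSpec(**dict(cfg.get("noise", {})))


def build_grid(cfg: dict) -> ParameterGrid:
    section = dict(cfg.get("grid", {}))
    if not section:
        return DEFAULT_GRID
    return ParameterGrid(
        f_prom=tuple(section["f_prom"]),
        f_elong=tuple(section["f_elong"]),
        t_prom=tuple(section["t_prom"]),
        t_elong=tuple(section["t_elong"]),
        seed_offsets=tuple(section.get("seed_offsets", (0,))),
    )
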