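"""Configuration loading: shipped defaults plus user TOML overrides."""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .cable import SolverConfig
from .field import DiscElectrode
from .membrane import RegionChannelParams
from .morphology import REGIONS, SectionSpec, TrajectorySpec
from .threshold import ElectrodeGrid

__all__ = ["load_config", "default_config", "ConfigError", "build_objects"]


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    with resources.files("rgcstim").joinpath("defaults.toml").open("rb") as fh:
        return tomllib.load(fh)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{where} must be a table")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Shipped defaults, optionally overridden by a user TOML file.

    Unknown keys are rejected with the offending key named.
    """
    cfg = default_config()
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        cfg = _merge(cfg, user)
    return cfg


def build_objects(cfg: dict) -> dict:
    """Instantiate the model objects described by a config dict."""
    sections = []
    for region in ("soma", "hillock", "socb", "narrow", "axon"):
        sec = cfg["sections"][region]
        d0 = sec.get("proximal_diameter", sec.get("diameter"))
        d1 = sec.get("distal_diameter", sec.get("diameter"))
        sections.append(SectionSpec(region, sec["length"], d0, d1))
    trajectory = TrajectorySpec(**cfg["trajectory"])
    channels = {r: RegionChannelParams(**cfg["channels"][r]) for r in REGIONS}
    dx = dict(cfg["discretization"])
    pulse_kw = dict(cfg["pulse"])
    electrode = DiscElectrode(center=(0.0, 0.0, cfg["electrode"]["height"]),
                              diameter=cfg["electrode"]["diameter"],
                              sigma=cfg["electrode"]["sigma"])
    solver = SolverConfig(**cfg["solver"])
    grid = ElectrodeGrid(step=cfg["grid"]["step"],
                         extent=(cfg["grid"]["extent_x"], cfg["grid"]["extent_y"]),
                         height=cfg["electrode"]["height"])
    return {"sections": sections, "trajectory": trajectory, "channels": channels,
            "per_region_dx": dx, "pulse_kwargs": pulse_kw, "electrode": electrode,
            "solver": solver, "grid": grid, "ca_e": cfg["membrane"]["ca_e"],
            "tolerance": cfg["threshold"]["tolerance"]}
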