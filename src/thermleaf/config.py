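"""YAML configuration loading, validation and round-tripping.

Schema (every section optional; defaults fill the gaps)::

    parameters:
      vcmax: {c: 27.68, dha: 57.96, unit: "umol m-2 s-1"}
      jmax: {...}  gamma_star: {...}  kc: {...}  ko: {...}  rl: {...}
    environment:
      t_leaf: 25.0
      ca_ppm: 410.0
      o2_kpa: 21.27
      pressure_kpa: 101.325
      ci_ratio: 0.7
    strategies:
      MYSTRAT:
        jmax: {c: 21.74, dha: 41.76}
    canopy:
      lai: 6.0
      n_layers: 10
      k_ext: 0.65
      theta: 0.7
      alpha: 0.3
    weather:
      mean_temp: 21.28
      n_days: 150
      diurnal_amp: 6.0
      seasonal_amp: 4.0
      noise_sd: 2.0
      q_peak: 1800.0
      photoperiod_h: 14.0
    season:
      conversion: 0.050

Unknown keys anywhere are rejected with the offending key named, so typos
never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .canopy import CanopyConfig
from .errors import ConfigError
from .fvcb import ArrheniusParam, LeafEnvironment, ParameterSet
from .defaults import wt_parameters
from .season import YIELD_CONVERSION
from .strategies import Strategy

__all__ = ["AnalysisConfig", "WeatherConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class WeatherConfig:
    """Defaults handed to the synthetic weather generator."""

    mean_temp: float = 21.28
    n_days: int = 150
    diurnal_amp: float = 6.0
    seasonal_amp: float = 4.0
    noise_sd: float = 2.0
    q_peak: float = 1800.0
    photoperiod_h: float = 14.0

    def kwargs(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SeasonConfig:
    conversion: float = YIELD_CONVERSION


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated aggregate of every module's configuration."""

    parameters: ParameterSet = field(default_factory=wt_parameters)
    environment: LeafEnvironment = field(default_factory=LeafEnvironment)
    strategies: dict[str, Strategy] = field(default_factory=dict)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    season: SeasonConfig = field(default_factory=SeasonConfig)


def _require_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in '{where}'; "
            f"allowed: {sorted(allowed)}"
        )


def _arrhenius(entry: dict, where: str, default: ArrheniusParam) -> ArrheniusParam:
    if not isinstance(entry, dict):
        raise ConfigError(f"'{where}' must be a mapping with c/dha")
    _require_keys(entry, {"c", "dha", "unit"}, where)
    try:
        return ArrheniusParam(
            c=float(entry.get("c", default.c)),
            dha=float(entry.get("dha", default.dha)),
            unit_label=str(entry.get("unit", default.unit_label)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid Arrhenius entry at '{where}': {exc}") from exc


def _build(cls, section: dict, mapping: dict[str, str], where: str):
    """Construct a validating dataclass from a config section."""
    _require_keys(section, set(mapping), where)
    kwargs = {mapping[k]: section[k] for k in section}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{where}' section: {exc}") from exc


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load and validate a YAML config; ``None`` or empty file → defaults."""
    if path is None:
        return AnalysisConfig()
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    _require_keys(
        raw,
        {"parameters", "environment", "strategies", "canopy", "weather", "season"},
        "top level",
    )

    base = wt_parameters()
    psec = raw.get("parameters", {}) or {}
    _require_keys(psec, set(ParameterSet.ROLES), "parameters")
    overrides = {
        role: _arrhenius(psec[role], f"parameters.{role}", getattr(base, role))
        for role in psec
    }
    parameters = base.with_overrides(overrides) if overrides else base

    env_map = {
        "t_leaf": "t_leaf",
        "ca_ppm": "ca",
        "o2_kpa": "o2",
        "pressure_kpa": "pressure",
        "ci_ratio": "ci_ratio",
    }
    environment = _build(
        LeafEnvironment, raw.get("environment", {}) or {}, env_map, "environment"
    )

    strategies: dict[str, Strategy] = {}
    for name, roles in (raw.get("strategies", {}) or {}).items():
        if not isinstance(roles, dict):
            raise ConfigError(f"'strategies.{name}' must map roles to c/dha")
        _require_keys(roles, set(ParameterSet.ROLES), f"strategies.{name}")
        strategies[name] = Strategy(
            name,
            {
                role: _arrhenius(
                    entry, f"strategies.{name}.{role}", getattr(base, role)
                )
                for role, entry in roles.items()
            },
        )

    canopy = _build(
        CanopyConfig, raw.get("canopy", {}) or {},
        {k: k for k in ("lai", "n_layers", "k_ext", "theta", "alpha")}, "canopy",
    )
    weather = _build(
        WeatherConfig, raw.get("weather", {}) or {},
        {f.name: f.name for f in dataclasses.fields(WeatherConfig)}, "weather",
    )
    season = _build(
        SeasonConfig, raw.get("season", {}) or {}, {"conversion": "conversion"},
        "season",
    )
    return AnalysisConfig(
        parameters=parameters,
        environment=environment,
        strategies=strategies,
        canopy=canopy,
        weather=weather,
        season=season,
    )


def config_to_dict(config: AnalysisConfig) -> dict:
    """The canonical YAML-ready representation of a config."""
    p = config.parameters
    env = config.environment
    return {
        "parameters": {
            role: {
                "c": getattr(p, role).c,
                "dha": getattr(p, role).dha,
                "unit": getattr(p, role).unit_label,
            }
            for role in ParameterSet.ROLES
        },
        "environment": {
            "t_leaf": env.t_leaf,
            "ca_ppm": env.ca,
            "o2_kpa": env.o2,
            "pressure_kpa": env.pressure,
            "ci_ratio": env.ci_ratio,
        },
        "strategies": {
            name: {
                role: {"c": param.c, "dha": param.dha, "unit": param.unit_label}
                for role, param in strat.overrides.items()
            }
            for name, strat in config.strategies.items()
        },
        "canopy": dataclasses.asdict(config.canopy),
        "weather": dataclasses.asdict(config.weather),
        "season": dataclasses.asdict(config.season),
    }


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` of the result is identity."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False)
    )
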