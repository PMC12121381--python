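"""Season-scale integration of canopy assimilation and proxy yield.

Runs the multilayer canopy model through an hourly weather series (leaf
temperature taken equal to air temperature; no energy balance), integrates
the canopy CO2 flux over the season by the trapezoidal rule, and converts
the seasonal carbon gain to a "proxy yield" through a single fixed factor.

The proxy yield is a presentation device: the conversion is chosen so an
unmodified canopy under the ambient scenario lands near 5.5 t ha⁻¹, which
makes scenario tables read like crop-model output. Only *relative* and
*ordinal* statements (strategy X beats Y; warming lowers yield) are
meaningful at this level — the model has no phenology, water balance,
nitrogen or respiration budget behind that number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .canopy import CanopyConfig, canopy_rate_series
from .defaults import default_environment
from .fvcb import LeafEnvironment
from .strategies import Strategy, combine
from .weather import WeatherSeries, apply_scenario, generate_season, scenario_label

__all__ = [
    "YIELD_CONVERSION",
    "Scenario",
    "SeasonResult",
    "run_scenario",
    "scenario_table",
    "DEFAULT_SCENARIOS",
]

#: Proxy-yield conversion, t ha⁻¹ per (mol CO2 m⁻² ground season⁻¹); fixed so
#: the unmodified canopy under the ambient default season sits near 5.5 t ha⁻¹.
YIELD_CONVERSION = 0.0225

_SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class Scenario:
    """A climate scenario: constant warming offset and CO2 mole fraction."""

    delta_t: float = 0.0
    ca_ppm: float = 410.0

    @property
    def label(self) -> str:
        return scenario_label(self.delta_t, self.ca_ppm)


DEFAULT_SCENARIOS = (
    Scenario(0.0, 410.0),
    Scenario(0.0, 610.0),
    Scenario(5.0, 410.0),
    Scenario(5.0, 610.0),
)


@dataclass(frozen=True)
class SeasonResult:
    """Season-integrated carbon gain for one strategy × weather series."""

    strategy_label: str
    scenario_label: str
    carbon_gain: float  # mol CO2 m⁻² ground season⁻¹
    proxy_yield: float  # t ha⁻¹ equivalent
    daily_gain: np.ndarray  # mol CO2 m⁻² ground day⁻¹
    seed: int


def run_scenario(
    strategy_set: Iterable[Strategy | str],
    weather: WeatherSeries,
    canopy: CanopyConfig | None = None,
    env_defaults: LeafEnvironment | None = None,
    baseline=None,
    conversion: float = YIELD_CONVERSION,
) -> SeasonResult:
    """Integrate canopy assimilation over one weather series.

    Hourly canopy rates are computed with leaf temperature equal to air
    temperature and CO2 taken from the weather; nights contribute the day
    respiration term (at zero light the operating electron transport is
    zero, so the layer rate collapses to −R_l). The seasonal carbon gain is
    the trapezoidal time-integral of the hourly rates.
    """
    from .defaults import wt_parameters

    canopy = canopy or CanopyConfig()
    env = env_defaults or default_environment()
    params = combine(strategy_set, baseline or wt_parameters())
    rates = canopy_rate_series(
        params, env, canopy, weather.t_air, weather.q0, weather.ca
    )  # µmol m⁻² ground s⁻¹ per hour
    carbon_gain = float(np.trapezoid(rates, dx=_SECONDS_PER_HOUR) * 1e-6)
    n_days = len(rates) // 24
    daily = rates[: n_days * 24].reshape(n_days, 24).sum(axis=1) * _SECONDS_PER_HOUR * 1e-6
    return SeasonResult(
        strategy_label=params.label,
        scenario_label=weather.scenario_label,
        carbon_gain=carbon_gain,
        proxy_yield=conversion * carbon_gain,
        daily_gain=daily,
        seed=weather.seed,
    )


def _strategy_frozen(strategy_set: Iterable[Strategy | str]) -> tuple:
    from .strategies import builtin

    return tuple(
        sorted(s.name if isinstance(s, Strategy) else builtin(s).name
               for s in strategy_set)
    )


def scenario_table(
    strategy_sets: Sequence[Iterable[Strategy | str]],
    scenarios: Sequence[Scenario] = DEFAULT_SCENARIOS,
    replicate_seeds: Sequence[int] = tuple(range(1, 11)),
    canopy: CanopyConfig | None = None,
    env_defaults: LeafEnvironment | None = None,
    conversion: float = YIELD_CONVERSION,
    **weather_kwargs,
) -> pd.DataFrame:
    """Mean ± sd change in proxy yield versus the unmodified baseline.

    For every scenario and replicate seed, one base season is generated,
    the scenario transform applied, and each strategy set integrated; the
    table reports mean and sd over seeds of
    ``proxy_yield(strategy) − proxy_yield(WT)``. The WT (empty) strategy
    set must be among ``strategy_sets`` and its row is exactly zero.

    Columns: strategy, scenario, mean_delta_proxy_yield, sd, n_seeds.
    """
    if not replicate_seeds:
        raise ValueError("need at least one replicate seed")
    keys = [_strategy_frozen(s) for s in strategy_sets]
    if () not in keys and ("WT",) not in keys:
        raise ValueError("strategy_sets must include the WT (empty) baseline")

    records: list[dict] = []
    for seed in replicate_seeds:
        base = generate_season(seed=seed, **weather_kwargs)
        for scen in scenarios:
            weather = apply_scenario(base, scen.delta_t, scen.ca_ppm)
            yields = {}
            labels = {}
            for key, sset in zip(keys, strategy_sets):
                res = run_scenario(
                    sset, weather, canopy=canopy, env_defaults=env_defaults,
                    conversion=conversion,
                )
                yields[key] = res.proxy_yield
                labels[key] = res.strategy_label
            wt_key = () if () in yields else ("WT",)
            for key in keys:
                records.append(
                    {
                        "strategy": labels[key],
                        "scenario": scen.label,
                        "seed": seed,
                        "delta": yields[key] - yields[wt_key],
                        "proxy_yield": yields[key],
                    }
                )
    df = pd.DataFrame(records)
    out = (
        df.groupby(["strategy", "scenario"], sort=False)
        .agg(
            mean_delta_proxy_yield=("delta", "mean"),
            sd=("delta", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
            mean_proxy_yield=("proxy_yield", "mean"),
            n_seeds=("seed", "count"),
        )
        .reset_index()
    )
    return out
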