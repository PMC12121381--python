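"""Synthetic hourly growing-season weather and climate-scenario transforms.

The generator emulates the statistical skeleton a Midwest US soybean season
hands to a canopy model: a seasonal mean air temperature (21.28°C by
default), a seasonal sinusoid peaking mid-season, a diurnal sinusoid peaking
mid-afternoon, iid Gaussian hour-to-hour noise, and a half-sinusoid light
curve over a fixed photoperiod. Climate scenarios are the standard
warming/fertilization transforms: a constant temperature offset (+5°C) and
a replacement CO2 mole fraction (410 vs 610 ppm).

Humidity, wind, rainfall and soil water are deliberately absent — water
stress is outside this package's scope — so interannual variance across
seeds is smaller than a weather record's.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["WeatherSeries", "generate_season", "apply_scenario", "scenario_label"]

#: Canonical labels for the four standard climate scenarios.
_SCENARIO_LABELS = {
    (0.0, 410.0): "Amb",
    (0.0, 610.0): "Elev",
    (5.0, 410.0): "Amb + Heat",
    (5.0, 610.0): "Elev + Heat",
}


@dataclass(frozen=True)
class WeatherSeries:
    """Hourly air temperature, light and CO2 over one growing season."""

    timestamps: pd.DatetimeIndex
    t_air: np.ndarray
    q0: np.ndarray
    ca: np.ndarray
    seed: int
    scenario_label: str = "Amb"

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if not (len(self.t_air) == len(self.q0) == len(self.ca) == n):
            raise ValueError("weather arrays must share one length")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.q0 < 0):
            raise ValueError("light must be >= 0 everywhere")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "t_air_c": self.t_air,
                "q0_umol_m2_s": self.q0,
                "ca_ppm": self.ca,
            }
        )


def scenario_label(delta_t: float, ca_ppm: float) -> str:
    """Canonical scenario name, e.g. (5, 610) → 'Elev + Heat'."""
    key = (float(delta_t), float(ca_ppm))
    if key in _SCENARIO_LABELS:
        return _SCENARIO_LABELS[key]
    return f"dT={delta_t:+g}°C, {ca_ppm:g} ppm"


def generate_season(
    mean_temp: float = 21.28,
    n_days: int = 150,
    seed: int = 0,
    diurnal_amp: float = 6.0,
    seasonal_amp: float = 4.0,
    noise_sd: float = 2.0,
    q_peak: float = 1800.0,
    photoperiod_h: float = 14.0,
    ca_ppm: float = 410.0,
    start: str = "2000-05-15",
) -> WeatherSeries:
    """Generate one synthetic growing season of hourly weather.

    Air temperature is ``mean_temp`` plus a seasonal sinusoid (one full
    period over the season, peaking at mid-season), a diurnal sinusoid
    peaking at 15:00, and seeded iid Gaussian noise; each component averages
    to zero so the realized seasonal mean tracks ``mean_temp``. Light is a
    half-sinusoid over a photoperiod centred on solar noon, exactly zero
    outside it; CO2 is constant.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    if diurnal_amp < 0 or seasonal_amp < 0 or noise_sd < 0:
        raise ValueError("amplitudes and noise_sd must be >= 0")
    if not (0 < photoperiod_h <= 24):
        raise ValueError(f"photoperiod must be in (0, 24] h, got {photoperiod_h}")

    n_hours = n_days * 24
    timestamps = pd.date_range(start=start, periods=n_hours, freq="h")
    hour = np.arange(n_hours) % 24
    day_frac = np.arange(n_hours) / n_hours  # fraction of the season elapsed

    rng = np.random.default_rng(seed)
    seasonal = seasonal_amp * np.sin(2 * np.pi * (day_frac - 0.25))
    diurnal = diurnal_amp * np.cos(2 * np.pi * (hour - 15) / 24)
    noise = rng.normal(0.0, noise_sd, n_hours) if noise_sd > 0 else np.zeros(n_hours)
    t_air = mean_temp + seasonal + diurnal + noise

    sunrise = 12.0 - photoperiod_h / 2
    phase = (hour - sunrise) / photoperiod_h
    q0 = np.where(
        (phase >= 0) & (phase <= 1), q_peak * np.sin(np.pi * np.clip(phase, 0, 1)), 0.0
    )
    q0 = np.maximum(q0, 0.0)

    return WeatherSeries(
        timestamps=timestamps,
        t_air=t_air,
        q0=q0,
        ca=np.full(n_hours, float(ca_ppm)),
        seed=seed,
        scenario_label=scenario_label(0.0, ca_ppm),
    )


def apply_scenario(
    series: WeatherSeries, delta_t: float = 0.0, ca_ppm: float | None = None
) -> WeatherSeries:
    """Shift temperature by a constant and/or replace the CO2 mole fraction.

    Light and timestamps are untouched; the label is updated to the
    canonical scenario name.
    """
    ca_value = float(ca_ppm) if ca_ppm is not None else float(series.ca[0])
    return replace(
        series,
        t_air=series.t_air + delta_t,
        ca=np.full(len(series), ca_value),
        scenario_label=scenario_label(delta_t, ca_value),
    )
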