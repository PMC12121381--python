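"""Leaf-level temperature-response analysis.

Sweeps the FvCB model over a leaf-temperature grid, locates the thermal
optimum (T_max, A_max), reports relative gains of engineered parameter sets
over a reference at chosen temperatures, and finds the temperatures where
the limiting process switches between rubisco carboxylation and RuBP
regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedGainError
from .fvcb import (
    COLIMITATION_EPS,
    LeafEnvironment,
    Limitation,
    ParameterSet,
    assimilation_arrays,
)

__all__ = [
    "TemperatureResponseCurve",
    "ThermalOptimum",
    "temperature_sweep",
    "find_optimum",
    "relative_gain",
    "limitation_crossover",
]

DEFAULT_T_MIN = 10.0
DEFAULT_T_MAX = 45.0
DEFAULT_STEP = 0.1


@dataclass(frozen=True)
class TemperatureResponseCurve:
    """Gridded A_N, A_c, A_j and limitation state over leaf temperature."""

    grid: np.ndarray
    a_n: np.ndarray
    a_c: np.ndarray
    a_j: np.ndarray
    limitation: list[Limitation]
    label: str
    environment: LeafEnvironment

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        n = len(self.grid)
        if not (len(self.a_n) == len(self.a_c) == len(self.a_j) == n
                and len(self.limitation) == n):
            raise ValueError("curve arrays must share the grid's length")

    def interp_a_n(self, t: float) -> float:
        """A_N at temperature ``t``, linearly interpolated on the grid."""
        if not (self.grid[0] <= t <= self.grid[-1]):
            raise ValueError(f"t={t} outside the swept range")
        return float(np.interp(t, self.grid, self.a_n))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per grid point."""
        return pd.DataFrame(
            {
                "strategy": self.label,
                "t_leaf_c": self.grid,
                "a_n": self.a_n,
                "a_c": self.a_c,
                "a_j": self.a_j,
                "limitation": [lim.value for lim in self.limitation],
            }
        )


@dataclass(frozen=True)
class ThermalOptimum:
    """Location and value of a curve's maximum A_N."""

    t_opt: float
    a_max: float
    at_boundary: bool = False


def temperature_sweep(
    params: ParameterSet,
    env: LeafEnvironment,
    t_min: float = DEFAULT_T_MIN,
    t_max: float = DEFAULT_T_MAX,
    step: float = DEFAULT_STEP,
) -> TemperatureResponseCurve:
    """Evaluate net assimilation on a uniform leaf-temperature grid.

    Everything in ``env`` except leaf temperature is held fixed. The default
    grid is 10–45°C at 0.1°C.
    """
    if not (t_min < t_max):
        raise ValueError(f"need t_min < t_max, got {t_min} >= {t_max}")
    if not (0 < step <= t_max - t_min):
        raise ValueError(f"invalid step {step} for range {t_min}–{t_max}")
    n = int(round((t_max - t_min) / step))
    grid = t_min + step * np.arange(n + 1)
    grid = grid[grid <= t_max + 1e-9]
    a_n, a_c, a_j = assimilation_arrays(params, env, grid)
    diff = a_c - a_j
    limitation = [
        Limitation.RUBISCO if d < -COLIMITATION_EPS
        else Limitation.RUBP if d > COLIMITATION_EPS
        else Limitation.COLIMITED
        for d in diff
    ]
    return TemperatureResponseCurve(
        grid=grid, a_n=a_n, a_c=a_c, a_j=a_j,
        limitation=limitation, label=params.label, environment=env,
    )


def find_optimum(curve: TemperatureResponseCurve) -> ThermalOptimum:
    """Locate (T_max, A_max) of a response curve.

    The grid argmax is refined by a quadratic through the argmax and its two
    neighbours; ties break to the lowest temperature. A maximum on the first
    or last grid point is returned as-is with ``at_boundary=True`` (the
    sweep did not bracket the optimum).
    """
    if len(curve.grid) < 3:
        raise ValueError("need at least 3 grid points to locate an optimum")
    i = int(np.argmax(curve.a_n))  # argmax returns the first (lowest-T) tie
    if i == 0 or i == len(curve.grid) - 1:
        return ThermalOptimum(
            t_opt=float(curve.grid[i]), a_max=float(curve.a_n[i]),
            at_boundary=True,
        )
    x = curve.grid[i - 1 : i + 2]
    y = curve.a_n[i - 1 : i + 2]
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:  # flat/degenerate neighbourhood; keep the grid point
        return ThermalOptimum(float(curve.grid[i]), float(curve.a_n[i]))
    t_opt = -b / (2 * a)
    return ThermalOptimum(
        t_opt=float(t_opt), a_max=float(a * t_opt**2 + b * t_opt + c)
    )


def relative_gain(
    test: TemperatureResponseCurve,
    reference: TemperatureResponseCurve,
    t: float,
) -> float:
    """Percent gain of ``test`` over ``reference`` at temperature ``t``.

    ``100 · (A_N,test(t) − A_N,ref(t)) / A_N,ref(t)`` with both rates
    linearly interpolated on the shared grid.
    """
    if len(test.grid) != len(reference.grid) or not np.allclose(
        test.grid, reference.grid
    ):
        raise ValueError("curves must share the same temperature grid")
    if test.environment != reference.environment:
        raise ValueError("curves must share the same leaf environment")
    ref = reference.interp_a_n(t)
    if ref <= 0:
        raise UndefinedGainError(
            f"reference A_N at {t}°C is {ref:.4g} <= 0; relative gain undefined"
        )
    return 100.0 * (test.interp_a_n(t) - ref) / ref


def limitation_crossover(curve: TemperatureResponseCurve) -> list[float]:
    """Temperatures where the limiting process switches.

    Sign changes of A_c − A_j between adjacent grid points, located by
    linear interpolation; an empty list means one limb limits throughout.
    """
    d = curve.a_c - curve.a_j
    crossings: list[float] = []
    for i in range(len(d) - 1):
        if d[i] == 0.0:
            crossings.append(float(curve.grid[i]))
        elif d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            crossings.append(
                float(curve.grid[i] + frac * (curve.grid[i + 1] - curve.grid[i]))
            )
    if d[-1] == 0.0:
        crossings.append(float(curve.grid[-1]))
    return crossings


def summary_table(
    curves: dict[str, TemperatureResponseCurve],
    reference_label: str = "WT",
    gain_temperatures: tuple[float, ...] = (35.0, 40.0),
) -> pd.DataFrame:
    """Per-strategy optimum and gains over the reference curve.

    Columns: strategy, t_opt_c, a_max, gain_vs_<ref>_<T>c_pct.
    """
    if reference_label not in curves:
        raise ValueError(f"reference '{reference_label}' not among curves")
    ref = curves[reference_label]
    rows = []
    for label, curve in curves.items():
        opt = find_optimum(curve)
        row = {"strategy": label, "t_opt_c": opt.t_opt, "a_max": opt.a_max}
        for t in gain_temperatures:
            key = f"gain_vs_{reference_label.lower()}_{t:g}c_pct"
            row[key] = relative_gain(curve, ref, t)
        rows.append(row)
    return pd.DataFrame(rows)
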