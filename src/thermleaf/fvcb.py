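"""Steady-state FvCB model of C3 leaf photosynthesis with Arrhenius kinetics.

Net CO2 assimilation is the minimum of the rubisco-carboxylation-limited rate

    A_c = (C - Γ*) V_cmax / (C + K_C (1 + O / K_O)) - R_l

and the RuBP-regeneration-limited rate at saturating light

    A_j = (C - Γ*) J_max / (4 C + 8 Γ*) - R_l,

where C and Γ* are the chloroplast CO2 partial pressure and the CO2
compensation point in the absence of day respiration (Pa), O the O2 partial
pressure (kPa), K_C / K_O rubisco's Michaelis constants for CO2 (Pa) and O2
(kPa), V_cmax the maximum carboxylation rate, J_max the light-saturated
electron-transport rate and R_l day respiration (all µmol m⁻² s⁻¹).

Each of the six kinetic parameters follows an Arrhenius temperature response

    value(T) = exp(c - ΔH_a / (R T_k)),

with scaling constant ``c`` (dimensionless), activation energy ``ΔH_a``
(kJ mol⁻¹), gas constant R = 8.314 J mol⁻¹ K⁻¹ and leaf temperature T_k in
kelvin. Triose-phosphate-utilization limitation, mesophyll conductance and
peaked (deactivation-type) responses are deliberately out of scope; the model
targets the high-temperature regime where A_c and A_j dominate.

All rate functions accept a scalar or an ndarray leaf temperature and
broadcast; scalar inputs return Python floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Union

import numpy as np

from .errors import ParameterRangeError, UnitMismatchError

__all__ = [
    "R_GAS",
    "KELVIN_OFFSET",
    "COLIMITATION_EPS",
    "Limitation",
    "ArrheniusParam",
    "ParameterSet",
    "LeafEnvironment",
    "AssimilationResult",
    "arrhenius_value",
    "rubisco_limited_rate",
    "rubp_limited_rate",
    "net_assimilation",
]

R_GAS = 8.314
"""Molar gas constant, J mol⁻¹ K⁻¹."""

KELVIN_OFFSET = 273.15

#: Classification tolerance for co-limitation, µmol m⁻² s⁻¹. Used only to
#: label the limiting process; A_N itself is always the exact minimum.
COLIMITATION_EPS = 1e-6

# Leaf temperatures a steady-state C3 leaf model can sensibly be asked about.
_T_MIN_C, _T_MAX_C = -50.0, 60.0

# exp() overflows doubles near 709; anything close means a nonsensical c.
_MAX_EXPONENT = 700.0

ArrayLike = Union[float, np.ndarray]


class Limitation(str, Enum):
    """Which FvCB limb limits net assimilation at a given temperature."""

    RUBISCO = "rubisco"
    RUBP = "rubp"
    COLIMITED = "colimited"


@dataclass(frozen=True)
class ArrheniusParam:
    """One kinetic parameter's Arrhenius temperature response.

    Parameters
    ----------
    c
        Dimensionless scaling constant (sets the magnitude; ``exp(c)`` is the
        infinite-temperature asymptote).
    dha
        Activation energy ΔH_a in kJ mol⁻¹ (sets the steepness); must be
        non-negative, so the evaluated value increases with temperature.
    unit_label
        The parameter's natural unit, e.g. ``"Pa"`` or ``"umol m-2 s-1"``.
        Used to catch unit-inconsistent parameter sets at equation boundaries.
    """

    c: float
    dha: float
    unit_label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.c) or not np.isfinite(self.dha):
            raise ValueError("ArrheniusParam requires finite c and dha")
        if self.dha < 0:
            raise ValueError(f"activation energy must be >= 0, got {self.dha}")

    def value(self, t_leaf: ArrayLike) -> ArrayLike:
        """Evaluate at leaf temperature ``t_leaf`` (°C)."""
        return arrhenius_value(self, t_leaf)


def arrhenius_value(param: ArrheniusParam, t_leaf: ArrayLike) -> ArrayLike:
    """Evaluate ``exp(c - ΔH_a / (R T_k))`` at leaf temperature(s) in °C.

    ΔH_a is given in kJ mol⁻¹ and converted to J mol⁻¹ against
    R = 8.314 J mol⁻¹ K⁻¹. Strictly increasing in temperature for ΔH_a > 0
    and strictly positive everywhere.

    Raises
    ------
    ValueError
        For non-finite or physically absurd temperatures (outside −50..60°C).
    ParameterRangeError
        If the exponent would overflow a double (absurd scaling constant).
    """
    t = np.asarray(t_leaf, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("leaf temperature must be finite")
    if np.any(t <= _T_MIN_C) or np.any(t >= _T_MAX_C):
        raise ValueError(
            f"leaf temperature outside the supported range "
            f"({_T_MIN_C}..{_T_MAX_C}°C)"
        )
    exponent = param.c - param.dha * 1e3 / (R_GAS * (t + KELVIN_OFFSET))
    if np.any(exponent > _MAX_EXPONENT):
        raise ParameterRangeError(
            f"Arrhenius evaluation overflows for parameter with c={param.c}, "
            f"dha={param.dha} {param.unit_label or ''}".rstrip()
        )
    out = np.exp(exponent)
    return float(out) if np.isscalar(t_leaf) or out.ndim == 0 else out


@dataclass(frozen=True)
class ParameterSet:
    """The six temperature-dependent FvCB parameters for one genotype.

    V_cmax, J_max and R_l are in µmol m⁻² s⁻¹, Γ* and K_C in Pa, K_O in kPa.
    """

    vcmax: ArrheniusParam
    jmax: ArrheniusParam
    gamma_star: ArrheniusParam
    kc: ArrheniusParam
    ko: ArrheniusParam
    rl: ArrheniusParam
    label: str = "WT"

    ROLES = ("vcmax", "jmax", "gamma_star", "kc", "ko", "rl")

    def __post_init__(self) -> None:
        # every entry must evaluate finite over the working range
        probe = np.array([0.0, 50.0])
        for role in self.ROLES:
            param = getattr(self, role)
            v = arrhenius_value(param, probe)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"parameter '{role}' is non-finite on 0–50°C")

    def evaluate(self, t_leaf: ArrayLike) -> dict:
        """All six parameter values at ``t_leaf`` (°C)."""
        return {role: getattr(self, role).value(t_leaf) for role in self.ROLES}

    def with_overrides(
        self, overrides: Mapping[str, ArrheniusParam], label: str | None = None
    ) -> "ParameterSet":
        """A copy with the given parameter roles replaced."""
        unknown = set(overrides) - set(self.ROLES)
        if unknown:
            raise ValueError(f"unknown parameter roles: {sorted(unknown)}")
        return replace(self, **overrides, label=label or self.label)


@dataclass(frozen=True)
class LeafEnvironment:
    """Leaf-level driving environment.

    Attributes
    ----------
    t_leaf
        Leaf temperature, °C.
    ca
        Ambient CO2 mole fraction, µmol mol⁻¹.
    o2
        O2 partial pressure, kPa (21% of a standard atmosphere by default).
    pressure
        Atmospheric pressure, kPa.
    ci_ratio
        Intercellular-to-ambient CO2 ratio; the model operates on
        C = ca · ci_ratio expressed as a partial pressure. 0.7 is the
        standard C3 operating point; 1.0 means C is taken as ambient.
    """

    t_leaf: float = 25.0
    ca: float = 410.0
    o2: float = 21.27
    pressure: float = 101.325
    ci_ratio: float = 0.7

    def __post_init__(self) -> None:
        if not (self.ca > 0):
            raise ValueError(f"ca must be > 0, got {self.ca}")
        if not (0 < self.ci_ratio <= 1):
            raise ValueError(f"ci_ratio must be in (0, 1], got {self.ci_ratio}")
        if self.o2 < 0:
            raise ValueError(f"o2 must be >= 0, got {self.o2}")
        if not (self.pressure > 0):
            raise ValueError(f"pressure must be > 0, got {self.pressure}")

    @property
    def co2_pa(self) -> float:
        """Operating CO2 partial pressure C, Pa."""
        return self.ca * self.ci_ratio * 1e-6 * self.pressure * 1e3

    def at(self, t_leaf: float) -> "LeafEnvironment":
        """Same environment at a different leaf temperature."""
        return replace(self, t_leaf=t_leaf)


@dataclass(frozen=True)
class AssimilationResult:
    """Net assimilation and its decomposition at one leaf temperature."""

    a_n: float
    a_c: float
    a_j: float
    limitation: Limitation
    evaluated_params: dict = field(repr=False)

    def __post_init__(self) -> None:
        assert self.a_n == min(self.a_c, self.a_j)


def _check_units(params: ParameterSet) -> None:
    """Reject parameter sets whose labels put gas constants in mixed units."""
    expectations = {"gamma_star": "Pa", "kc": "Pa", "ko": "kPa"}
    for role, expected in expectations.items():
        label = getattr(params, role).unit_label
        if label and label != expected:
            raise UnitMismatchError(
                f"parameter '{role}' is labelled '{label}' but the rate "
                f"equations require {expected}"
            )


def rubisco_limited_rate(params: ParameterSet, env: LeafEnvironment) -> float:
    """Rubisco-carboxylation-limited net rate A_c, µmol m⁻² s⁻¹.

    ``(C − Γ*) V_cmax / (C + K_C (1 + O/K_O)) − R_l`` with every parameter
    evaluated at ``env.t_leaf``. Negative values (below the compensation
    point) are legal and never clamped.
    """
    _check_units(params)
    p = params.evaluate(env.t_leaf)
    c_pa = env.co2_pa
    gross = (c_pa - p["gamma_star"]) * p["vcmax"] / (
        c_pa + p["kc"] * (1.0 + env.o2 / p["ko"])
    )
    return gross - p["rl"]


def rubp_limited_rate(params: ParameterSet, env: LeafEnvironment) -> float:
    """RuBP-regeneration-limited net rate A_j at saturating light.

    ``(C − Γ*) J_max / (4C + 8Γ*) − R_l`` evaluated at ``env.t_leaf``; the
    operating electron-transport rate J equals J_max (light-saturated form).
    """
    _check_units(params)
    p = params.evaluate(env.t_leaf)
    c_pa = env.co2_pa
    gross = (c_pa - p["gamma_star"]) * p["jmax"] / (
        4.0 * c_pa + 8.0 * p["gamma_star"]
    )
    return gross - p["rl"]


def classify_limitation(a_c: float, a_j: float, eps: float = COLIMITATION_EPS) -> Limitation:
    """Label which limb limits, with a tie band of width ``eps``."""
    if a_c < a_j - eps:
        return Limitation.RUBISCO
    if a_j < a_c - eps:
        return Limitation.RUBP
    return Limitation.COLIMITED


def net_assimilation(params: ParameterSet, env: LeafEnvironment) -> AssimilationResult:
    """Net assimilation A_N = min(A_c, A_j) with the limiting process labelled.

    The evaluated parameter values at ``env.t_leaf`` are returned for
    traceability.
    """
    a_c = rubisco_limited_rate(params, env)
    a_j = rubp_limited_rate(params, env)
    return AssimilationResult(
        a_n=min(a_c, a_j),
        a_c=a_c,
        a_j=a_j,
        limitation=classify_limitation(a_c, a_j),
        evaluated_params=params.evaluate(env.t_leaf),
    )


def assimilation_arrays(
    params: ParameterSet,
    env: LeafEnvironment,
    t_leaf: np.ndarray,
    co2_pa: ArrayLike | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (a_n, a_c, a_j) over an array of leaf temperatures.

    ``co2_pa`` overrides the environment's operating CO2 partial pressure
    (scalar or broadcastable array); used by the canopy/season layers where
    CO2 varies by climate scenario.
    """
    _check_units(params)
    t = np.asarray(t_leaf, dtype=float)
    p = params.evaluate(t)
    c_pa = env.co2_pa if co2_pa is None else np.asarray(co2_pa, dtype=float)
    a_c = (c_pa - p["gamma_star"]) * p["vcmax"] / (
        c_pa + p["kc"] * (1.0 + env.o2 / p["ko"])
    ) - p["rl"]
    a_j = (c_pa - p["gamma_star"]) * p["jmax"] / (
        4.0 * c_pa + 8.0 * p["gamma_star"]
    ) - p["rl"]
    return np.minimum(a_c, a_j), a_c, a_j
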