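"""Default kinetic constants and the calibrated leaf configuration.

The wild-type V_cmax, J_max and Γ* Arrhenius constants are the tobacco
values from in planta temperature-response measurements on plants expressing
a synthetic glycolate (photorespiratory bypass) pathway and their unmodified
controls. K_C, K_O and R_l are the standard in vivo tobacco temperature
responses from leaf gas-exchange studies; their published constants are in
mole-fraction units and are converted here once to partial pressures at a
standard atmosphere of 101.325 kPa by adding ``ln(0.101325)`` to the scaling
constant (a mole fraction of x µmol mol⁻¹ is x·P·10⁻⁶ expressed in the same
unit as P).

At 25°C the defaults evaluate to V_cmax ≈ 73.5, J_max ≈ 116.0 and
R_l ≈ 1.00 µmol m⁻² s⁻¹, Γ* ≈ 4.76 Pa, K_C ≈ 41.1 Pa, K_O ≈ 28.1 kPa —
the familiar tobacco magnitudes.
"""

from __future__ import annotations

import math

from .fvcb import ArrheniusParam, LeafEnvironment, ParameterSet

__all__ = [
    "STANDARD_PRESSURE_KPA",
    "wt_parameters",
    "default_environment",
    "calibrated_environment",
    "calibrated_parameters",
    "scale_day_respiration",
    "CALIBRATED_CI_RATIO",
    "CALIBRATED_RL_SCALE",
]

STANDARD_PRESSURE_KPA = 101.325

# ln(P) with P in the unit the published mole-fraction constants refer to
# (µmol mol⁻¹ → Pa and mmol mol⁻¹ → kPa share the same offset).
_MOLE_FRACTION_TO_PRESSURE = math.log(STANDARD_PRESSURE_KPA * 1e-3)

_RATE = "umol m-2 s-1"

# Wild-type constants: (c, ΔH_a kJ mol⁻¹).
_WT_CONSTANTS = {
    "vcmax": (27.68, 57.96, _RATE),
    "jmax": (21.6, 41.76, _RATE),
    "gamma_star": (15.6, 34.8, "Pa"),
    "kc": (38.05 + _MOLE_FRACTION_TO_PRESSURE, 79.43, "Pa"),
    "ko": (20.30 + _MOLE_FRACTION_TO_PRESSURE, 36.38, "kPa"),
    "rl": (18.72, 46.39, _RATE),
}

#: Intercellular-to-ambient CO2 ratio of the calibrated leaf configuration.
CALIBRATED_CI_RATIO = 0.7

#: Day-respiration scaling of the calibrated leaf configuration. The printed
#: relative gains of the engineering strategies are reproduced best with day
#: respiration omitted from the rate equations (the strategies alter gross
#: kinetics only, and R_l in the denominator inflates every relative gain).
CALIBRATED_RL_SCALE = 0.0

# Numerically-zero Arrhenius parameter: exp(-50) ≈ 2e-22, strictly positive.
_ZERO_RATE = ArrheniusParam(c=-50.0, dha=0.0, unit_label=_RATE)


def wt_parameters() -> ParameterSet:
    """The unmodified (wild-type) tobacco parameter set."""
    kwargs = {
        role: ArrheniusParam(c, dha, unit)
        for role, (c, dha, unit) in _WT_CONSTANTS.items()
    }
    return ParameterSet(label="WT", **kwargs)


def default_environment(t_leaf: float = 25.0) -> LeafEnvironment:
    """410 ppm CO2, 21% O2 (21.27 kPa), 101.325 kPa, ci_ratio 0.7."""
    return LeafEnvironment(t_leaf=t_leaf)


def scale_day_respiration(params: ParameterSet, scale: float) -> ParameterSet:
    """Scale R_l by a temperature-independent factor (0 allowed).

    Scaling multiplies the evaluated rate at every temperature, i.e. adds
    ``ln(scale)`` to the scaling constant; scale 0 substitutes a numerically
    zero parameter.
    """
    if scale < 0:
        raise ValueError(f"R_l scale must be >= 0, got {scale}")
    if scale == 0:
        rl = _ZERO_RATE
    else:
        rl = ArrheniusParam(
            params.rl.c + math.log(scale), params.rl.dha, params.rl.unit_label
        )
    return params.with_overrides({"rl": rl})


def calibrated_environment(t_leaf: float = 25.0) -> LeafEnvironment:
    """Leaf environment of the calibrated temperature-response analysis."""
    return LeafEnvironment(t_leaf=t_leaf, ci_ratio=CALIBRATED_CI_RATIO)


def calibrated_parameters(base: ParameterSet | None = None) -> ParameterSet:
    """Apply the calibrated R_l scaling to a parameter set (default WT)."""
    return scale_day_respiration(base or wt_parameters(), CALIBRATED_RL_SCALE)
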