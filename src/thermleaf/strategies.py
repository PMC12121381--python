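"""Engineered-thermotolerance strategies as composable parameter overrides.

Each strategy captures the FvCB-level signature of one engineering
intervention:

* ``RA`` — enhanced rubisco activation via a thermostable rubisco activase:
  a steeper, larger V_cmax temperature response (c=29.7, ΔH_a=62.88).
* ``PR`` — a photorespiratory bypass lowering the cost of oxygenation:
  a shallower Γ* response (c=13.3, ΔH_a=29.2) that drops below the
  wild-type Γ* above ≈19.7°C.
* ``RUBP`` — enhanced RuBP regeneration / electron transport: J_max scaled
  up uniformly (c=21.78, ΔH_a unchanged at 41.76; a ≈19.7% increase at every
  temperature).
* ``RUBP15`` — the alternative literal encoding of "a 15% increase in
  wild-type J_max" (c = 21.6 + ln 1.15). Not composable with ``RUBP``.

Strategies are combined onto a baseline parameter set; each built-in
overrides exactly one parameter role, so any subset of {RA, PR, RUBP} is a
valid stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import CompositionError
from .fvcb import ArrheniusParam, ParameterSet

__all__ = ["Strategy", "builtin", "builtin_names", "register", "combine"]

_RATE = "umol m-2 s-1"

#: Canonical ordering of strategy names in composite labels.
_CANONICAL_ORDER = ("RA", "PR", "RUBP", "RUBP15")


@dataclass(frozen=True)
class Strategy:
    """A named set of Arrhenius-parameter overrides."""

    name: str
    overrides: Mapping[str, ArrheniusParam] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "overrides", dict(self.overrides))
        unknown = set(self.overrides) - set(ParameterSet.ROLES)
        if unknown:
            raise ValueError(f"unknown parameter roles: {sorted(unknown)}")

    def __hash__(self) -> int:  # usable in sets; name identifies the strategy
        return hash(self.name)


_BUILTINS: dict[str, Strategy] = {
    "WT": Strategy("WT", {}),
    "RA": Strategy("RA", {"vcmax": ArrheniusParam(29.7, 62.88, _RATE)}),
    "PR": Strategy("PR", {"gamma_star": ArrheniusParam(13.3, 29.2, "Pa")}),
    "RUBP": Strategy("RUBP", {"jmax": ArrheniusParam(21.78, 41.76, _RATE)}),
    "RUBP15": Strategy(
        "RUBP15", {"jmax": ArrheniusParam(21.6 + math.log(1.15), 41.76, _RATE)}
    ),
}


def builtin(name: str) -> Strategy:
    """Look up a built-in or registered strategy by name."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown strategy '{name}'; known: {sorted(_BUILTINS)}"
        ) from None


def builtin_names() -> tuple[str, ...]:
    return tuple(_BUILTINS)


def register(strategy: Strategy, overwrite: bool = False) -> None:
    """Register a custom strategy (e.g. from a config file)."""
    if strategy.name in _BUILTINS and not overwrite:
        raise ValueError(f"strategy '{strategy.name}' already registered")
    _BUILTINS[strategy.name] = strategy


def _label(names: Iterable[str]) -> str:
    names = [n for n in names if n != "WT"]
    if not names:
        return "WT"
    ordered = [n for n in _CANONICAL_ORDER if n in names]
    extras = sorted(n for n in names if n not in _CANONICAL_ORDER)
    return "+".join(ordered + extras)


def combine(
    strategies: Iterable[Strategy | str], baseline: ParameterSet
) -> ParameterSet:
    """Apply a set of strategies to a baseline parameter set.

    The result is independent of input order; the label concatenates the
    strategy names in canonical order (RA, PR, RUBP). Two strategies that
    override the same parameter role conflict.
    """
    resolved = [s if isinstance(s, Strategy) else builtin(s) for s in strategies]
    overrides: dict[str, ArrheniusParam] = {}
    owners: dict[str, str] = {}
    for strat in sorted(resolved, key=lambda s: s.name):
        for role, param in strat.overrides.items():
            if role in owners:
                raise CompositionError(
                    f"strategies '{owners[role]}' and '{strat.name}' both "
                    f"override parameter '{role}'"
                )
            owners[role] = strat.name
            overrides[role] = param
    return baseline.with_overrides(
        overrides, label=_label(s.name for s in resolved)
    )
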