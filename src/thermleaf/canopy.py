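"""Simplified multilayer canopy scaling of leaf photosynthesis.

Light attenuates through the canopy following Beer–Lambert,
``Q(L) = Q0 · exp(−k·L)`` with cumulative leaf area index L measured from
the top; each layer's operating electron-transport rate J follows the
non-rectangular hyperbola light response; the RuBP-regeneration-limited
rate uses that J in place of J_max, and canopy assimilation is the
LAI-weighted sum over layers.

This is a deliberate, single-stream simplification of a full crop canopy
model: no sunlit/shaded split, no leaf-angle distribution, no within-canopy
temperature or CO2 profile, no energy balance. It exists to capture one
mechanism — shaded lower layers operate light-limited, where RuBP
regeneration (and hence Γ* and J_max) controls the rate — and its absolute
canopy rates should be read as illustrative, not predictive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fvcb import (
    COLIMITATION_EPS,
    LeafEnvironment,
    Limitation,
    ParameterSet,
)

__all__ = [
    "CanopyConfig",
    "LayerState",
    "light_profile",
    "operating_j",
    "canopy_assimilation",
]


@dataclass(frozen=True)
class CanopyConfig:
    """Canopy structure and electron-transport light-response parameters.

    Attributes
    ----------
    lai
        Total leaf area index, m² leaf m⁻² ground.
    n_layers
        Number of equal-LAI layers, indexed top-down.
    k_ext
        Beer–Lambert light extinction coefficient (0.65 is typical of a
        closed broadleaf canopy).
    theta
        Curvature of the non-rectangular hyperbola light response of J.
    alpha
        Initial quantum yield of electron transport,
        mol e⁻ (mol photons)⁻¹.
    """

    lai: float = 6.0
    n_layers: int = 10
    k_ext: float = 0.65
    theta: float = 0.7
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if self.lai < 0:
            raise ValueError(f"lai must be >= 0, got {self.lai}")
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")
        if not (0 < self.k_ext <= 1.5):
            raise ValueError(f"k_ext must be in (0, 1.5], got {self.k_ext}")
        if not (0 < self.theta < 1):
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if not (0 < self.alpha < 0.5):
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")

    def layer_midpoints(self) -> np.ndarray:
        """Cumulative LAI above each layer midpoint, top-down."""
        i = np.arange(self.n_layers)
        return (i + 0.5) * self.lai / self.n_layers


@dataclass(frozen=True)
class LayerState:
    """Per-layer light, electron transport and assimilation."""

    cum_lai: float
    q_layer: float
    j_layer: float
    a_n_layer: float
    limitation: Limitation


def light_profile(config: CanopyConfig, q0: float) -> np.ndarray:
    """Incident light at each layer midpoint, µmol photons m⁻² s⁻¹."""
    if q0 < 0:
        raise ValueError(f"q0 must be >= 0, got {q0}")
    return q0 * np.exp(-config.k_ext * config.layer_midpoints())


def operating_j(jmax_at_t, q, config: CanopyConfig):
    """Operating electron-transport rate from the non-rectangular hyperbola.

    The smaller root of ``θJ² − (αq + J_max)J + αq·J_max = 0``, computed in
    the cancellation-free form ``2αqJ_max / (αq + J_max + sqrt(disc))`` so it
    degrades gracefully to the rectangular hyperbola as θ → 0. J → αq in
    dim light and J → J_max under saturating light. Accepts arrays.
    """
    q = np.asarray(q, dtype=float)
    jmax = np.asarray(jmax_at_t, dtype=float)
    if np.any(q < 0):
        raise ValueError("light must be >= 0")
    if np.any(jmax <= 0):
        raise ValueError("jmax_at_t must be > 0")
    aq = config.alpha * q
    b = aq + jmax
    disc = b * b - 4.0 * config.theta * aq * jmax
    # roundoff can push the discriminant a hair negative near saturation
    rel = disc / np.where(b > 0, b * b, 1.0)
    if np.any(rel < -1e-12):
        raise FloatingPointError("negative discriminant in light response")
    disc = np.maximum(disc, 0.0)
    j = 2.0 * aq * jmax / (b + np.sqrt(disc))
    return float(j) if j.ndim == 0 else j


def canopy_assimilation(
    params: ParameterSet,
    env: LeafEnvironment,
    config: CanopyConfig,
    q0: float,
) -> tuple[float, list[LayerState]]:
    """Canopy-scale net assimilation, µmol CO2 m⁻² ground s⁻¹.

    Every layer shares the environment's temperature and CO2; only light
    differs. Returns the canopy rate and the per-layer states (top-down).
    """
    q_layers = light_profile(config, q0)
    cum = config.layer_midpoints()
    p = params.evaluate(env.t_leaf)
    c_pa = env.co2_pa
    a_c = (c_pa - p["gamma_star"]) * p["vcmax"] / (
        c_pa + p["kc"] * (1.0 + env.o2 / p["ko"])
    ) - p["rl"]
    j = operating_j(p["jmax"], q_layers, config)
    a_j = (c_pa - p["gamma_star"]) * j / (4.0 * c_pa + 8.0 * p["gamma_star"]) - p["rl"]
    a_n = np.minimum(a_c, a_j)
    d_lai = config.lai / config.n_layers
    layers = [
        LayerState(
            cum_lai=float(cum[i]),
            q_layer=float(q_layers[i]),
            j_layer=float(np.atleast_1d(j)[i]),
            a_n_layer=float(a_n[i]),
            limitation=(
                Limitation.RUBISCO if a_c - a_j[i] < -COLIMITATION_EPS
                else Limitation.RUBP if a_c - a_j[i] > COLIMITATION_EPS
                else Limitation.COLIMITED
            ),
        )
        for i in range(config.n_layers)
    ]
    return float(np.sum(a_n) * d_lai), layers


def canopy_rate_series(
    params: ParameterSet,
    env: LeafEnvironment,
    config: CanopyConfig,
    t_air: np.ndarray,
    q0: np.ndarray,
    ca_ppm: np.ndarray | float,
) -> np.ndarray:
    """Vectorized canopy rate over an hourly series (used by the season run).

    ``t_air``, ``q0`` (and optionally ``ca_ppm``) are aligned 1-D arrays;
    leaf temperature is taken equal to air temperature. Matches
    :func:`canopy_assimilation` applied hour by hour.
    """
    t = np.asarray(t_air, dtype=float)
    q = np.asarray(q0, dtype=float)
    p = params.evaluate(t)  # each entry shape (H,)
    ca = np.asarray(ca_ppm, dtype=float)
    c_pa = ca * env.ci_ratio * 1e-6 * env.pressure * 1e3
    a_c = (c_pa - p["gamma_star"]) * p["vcmax"] / (
        c_pa + p["kc"] * (1.0 + env.o2 / p["ko"])
    ) - p["rl"]  # (H,)
    cum = config.layer_midpoints()  # (L,)
    q_layers = q[:, None] * np.exp(-config.k_ext * cum)[None, :]  # (H, L)
    j = operating_j(p["jmax"][:, None], q_layers, config)
    gamma = p["gamma_star"][:, None]
    c_col = c_pa[:, None] if np.ndim(c_pa) else c_pa
    a_j = (c_col - gamma) * j / (4.0 * c_col + 8.0 * gamma) - p["rl"][:, None]
    a_n = np.minimum(a_c[:, None], a_j)  # (H, L)
    return a_n.sum(axis=1) * (config.lai / config.n_layers)
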