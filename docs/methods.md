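# Methods

## Leaf model

Net CO2 assimilation is the steady-state FvCB minimum of the
rubisco-carboxylation-limited rate and the RuBP-regeneration-limited rate
at saturating light,

```
A_c = (C − Γ*)·V_cmax / (C + K_C·(1 + O/K_O)) − R_l
A_j = (C − Γ*)·J_max  / (4C + 8Γ*)            − R_l
A_N = min(A_c, A_j),
```

with C and Γ* in Pa, O and K_O in kPa, and rates in µmol m⁻² s⁻¹. All six
kinetic parameters (V_cmax, J_max, Γ*, K_C, K_O, R_l) follow the Arrhenius
form `exp(c − ΔH_a/(R·T_k))`. The activation energies are stored in
kJ mol⁻¹ and converted (×10³) against R = 8.314 J mol⁻¹ K⁻¹: this is the
only unit reading under which the constants give physiologically sensible
magnitudes (V_cmax ≈ 74 µmol m⁻² s⁻¹ at 25°C). Triose-phosphate-utilization
limitation is omitted — it matters at saturating CO2 or low temperature,
not in the high-temperature regime this package targets — as are mesophyll
conductance, stomatal coupling, and peaked (deactivation-type) temperature
responses.

Internally all CO2-like quantities are Pa and O2-like quantities kPa,
converted once at the boundary at the stated atmospheric pressure (default
101.325 kPa). The rate equations are homogeneous in the gas unit, and a
dual-route test confirms that evaluating in mole fractions instead changes
A_N by less than 10⁻⁹ relative.

### Default constants

| parameter | c | ΔH_a (kJ mol⁻¹) | value at 25°C |
|---|---|---|---|
| V_cmax | 27.68 | 57.96 | 73.5 µmol m⁻² s⁻¹ |
| J_max | 21.6 | 41.76 | 116.0 µmol m⁻² s⁻¹ |
| Γ* | 15.6 | 34.8 | 4.76 Pa |
| K_C | 35.7606 | 79.43 | 41.1 Pa |
| K_O | 18.0106 | 36.38 | 28.1 kPa |
| R_l | 18.72 | 46.39 | 1.01 µmol m⁻² s⁻¹ |

V_cmax, J_max and Γ* are the tobacco wild-type responses measured alongside
the photorespiratory-bypass lines that anchor the PR strategy. K_C, K_O and
R_l are the standard in vivo tobacco parameterization; their published
scaling constants are in mole-fraction units (38.05, 20.30, 18.72) and the
K_C/K_O constants are shifted here by `ln(0.101325)` to express the
parameters directly in Pa/kPa at a standard atmosphere.

The operating CO2 is `C = ca · ci_ratio` expressed as a partial pressure,
with `ci_ratio = 0.7` by default (the standard C3 intercellular operating
point); `ci_ratio = 1.0` treats ambient CO2 as the operating concentration.
Default environment: 410 µmol mol⁻¹ CO2, O = 21.27 kPa (21% of a standard
atmosphere), saturating light. A_N below the compensation point is negative
and never clamped.

### Numerical conventions

* Co-limitation labelling uses a tie band ε = 10⁻⁶ µmol m⁻² s⁻¹; A_N is
  always the exact minimum regardless of label.
* Arrhenius evaluation guards the exponent at 700 (double overflow) and
  rejects leaf temperatures outside −50..60°C.
* `find_optimum` refines the grid argmax with a quadratic through its
  neighbours; ties break to the lowest temperature; a boundary maximum is
  returned flagged rather than refined.
* Printed-temperature gains (35, 40°C) use linear interpolation on the
  sweep grid, not the nearest grid point.

## Engineering strategies

Each strategy is a named override of one parameter's (c, ΔH_a):

* **RA** (enhanced rubisco activation): V_cmax → (29.7, 62.88). Mimics a
  thermostable rubisco activase maintaining carboxylation capacity at high
  temperature.
* **PR** (photorespiratory bypass): Γ* → (13.3, 29.2). A flatter
  compensation-point response; the engineered and wild-type Γ*(T) curves
  cross near 19.7°C, with the bypass Γ* lower above that.
* **RUBP** (enhanced RuBP regeneration): J_max c 21.6 → 21.78 at unchanged
  ΔH_a, a uniform ×1.197 scaling of J_max. The strategy is also described
  in the literature as "a 15% increase in J_max"; that literal encoding is
  provided as the registered `RUBP15` strategy (c = 21.6 + ln 1.15). The
  two differ by ~4% in J_max; the table-derived constant is the default and
  the two are deliberately not reconciled.

Strategies compose onto any baseline; conflicts (two overrides of one role)
are errors, composition is order-invariant, and composite labels are
canonical (RA, PR, RUBP order).

## Calibrated leaf configuration

Two choices the leaf-level gain analysis needs are genuinely
under-determined: whether the operating CO2 is intercellular (ci_ratio 0.7)
or ambient (1.0), and the magnitude of R_l, whose temperature constants are
not part of the strategy parameter table. A one-time grid calibration over
exactly these two axes (ci_ratio ∈ {0.7, 1.0}; R_l scale ∈ [0, 2] in steps
of 0.05) selected **ci_ratio = 0.7 with R_l scale 0** as the configuration
that best reproduces the published approximate gains of all strategy
combinations simultaneously (maximum deviation 2.6 percentage points over
the six values). The R_l-free choice is physically interpretable: the
strategies act on gross kinetics only, and a common R_l in both numerator
terms inflates every *relative* gain without changing the underlying
mechanism. `calibrated_parameters()` / `calibrated_environment()` expose
this configuration; R_l scale 0 is represented by a numerically zero
Arrhenius parameter (c = −50) so strict positivity is preserved. The
default (uncalibrated) parameter set keeps the literature R_l.

On this configuration the computed gains are PR +3.8% (35°C) and +6.5%
(40°C), RA +10.5% (35°C), RA+PR +14.6% (35°C) and +21.4% (40°C), and the
PR peak rate +1.6% — all within ±3 points of the published approximate
values. One structural claim does not survive the constants: the bypass Γ*
response is described as leaving the thermal optimum unchanged, but because
it alters the slope of Γ*(T) (not just its level), it shifts T_max up by
≈1.1°C under every admissible calibration. The package reports the computed
shift rather than forcing agreement, and the corresponding acceptance test
is expected to fail.

## Canopy layer

A single-stream Beer–Lambert canopy: `Q(L) = Q0·exp(−k·L)` with cumulative
LAI L from the top, layers of equal LAI with midpoints at
`(i+0.5)·lai/n_layers`. Defaults: LAI 6, 10 layers, k = 0.65 (closed
broadleaf canopy). Per layer, the operating electron transport J is the
smaller root of the non-rectangular hyperbola
`θJ² − (αQ + J_max)J + αQ·J_max = 0` (defaults θ = 0.7, α = 0.3), computed
in the conjugate form `2αQ·J_max/(αQ + J_max + √disc)` which is
cancellation-free and degrades exactly to the rectangular hyperbola as
θ → 0; discriminants more than 10⁻¹² relative below zero are an error,
smaller ones are clamped. A_j uses J in place of J_max; the canopy rate is
the LAI-weighted layer sum. Refining 10 → 100 layers moves the canopy rate
by < 1%.

Deliberately absent: sunlit/shaded partitioning, leaf angle distributions,
within-canopy temperature and CO2 profiles, energy balance, sun-fleck
dynamics and photosynthetic induction. The layer exists to carry one
mechanism — shaded layers run light-limited, so their assimilation is
controlled by the RuBP limb and hence by Γ* and J_max — and its absolute
rates carry no validation weight.

## Synthetic weather and season integration

One growing season is 150 days of hourly weather: air temperature =
seasonal mean (default 21.28°C) + a seasonal sinusoid (one period per
season, amplitude 4°C, peaking mid-season) + a diurnal sinusoid (amplitude
6°C, peaking 15:00) + iid Gaussian noise (sd 2°C, seeded); light is a
half-sinusoid over a 14 h photoperiod peaking at 1800 µmol m⁻² s⁻¹, exactly
zero at night; CO2 is constant 410 µmol mol⁻¹. Every sinusoid averages to
zero, so realized seasonal means sit within 0.2°C of the configured mean;
the defaults were chosen so seed-to-seed variation brackets the ~20–22.5°C
range of Midwest soybean seasonal means. Climate scenarios are exact
transforms: +ΔT at every hour and/or a replacement CO2 (Amb, Elev = 610
ppm, Amb + Heat = +5°C, Elev + Heat = both).

The generator emulates only the thermal/radiative skeleton of a season. It
has no humidity, wind, rainfall or soil water, so the water-stress-driven
component of real interannual yield variance — which field studies suggest
dominates — is absent by construction. Passing season-scale tests therefore
demonstrates the temperature × CO2 mechanism only, not field yield response.

Season runs take leaf temperature equal to air temperature (no energy
balance), evaluate the canopy hourly (nights collapse to −R_l per unit leaf
area, since J = 0 in the dark), and integrate by the trapezoidal rule.
"Proxy yield" is the seasonal carbon gain times a single fixed factor,
0.0225 t ha⁻¹ per mol CO2 m⁻², chosen once so the unmodified canopy under
the ambient scenario lands near 5.5 t ha⁻¹ for presentation comparability
with crop-model output; every scientific statement at this level is
relative or ordinal, never absolute. Replicate seeds default to 1–10,
structurally echoing a ten-season experiment.

## Known limitations

* Leaf kinetics are tobacco's; no species re-parameterization is included.
* The RA and RUBP parameter overrides are extrapolations from experimental
  evidence, not fitted temperature datasets; their gains inherit that
  uncertainty.
* The canopy/season layer cannot reproduce absolute yields or
  water-stress-year variance, and does not try to.
* Steady-state only: induction dynamics under fluctuating light, which
  likely favour the RA strategy, are not modelled.
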