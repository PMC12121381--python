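# thermleaf

Thermal tolerance of C3 photosynthesis, from leaf to canopy to growing
season.

Rising growing-season temperatures depress net CO2 assimilation (*A*_N) in
C3 crops, and three engineering strategies are on the table to push the
photosynthetic optimum upward: a more thermostable rubisco activase that
keeps rubisco activated at high temperature (**RA**), synthetic
photorespiratory bypasses that lower the CO2 cost of oxygenation (**PR**),
and overexpression targets that raise RuBP-regeneration / electron-transport
capacity (**RUBP**). `thermleaf` is a small library for asking, mechanistically,
what each strategy — and any stack of them — buys at the leaf level across
temperature, and how those leaf-level signatures propagate through a shaded
canopy and a warming growing season. It is aimed at plant physiologists and
crop modellers who want the strategy comparison on their desk, without a
full crop-simulator pipeline.

## The model

Light-saturated net assimilation is the minimum of the rubisco-limited and
RuBP-regeneration-limited rates of the Farquhar–von Caemmerer–Berry (FvCB)
model:

```
A_c = (C − Γ*)·V_cmax / (C + K_C·(1 + O/K_O)) − R_l
A_j = (C − Γ*)·J_max  / (4C + 8Γ*)            − R_l
A_N = min(A_c, A_j)
```

with every kinetic parameter following an Arrhenius temperature response
`exp(c − ΔH_a/(R·T_k))` (`c` dimensionless, `ΔH_a` in kJ mol⁻¹,
R = 8.314 J mol⁻¹ K⁻¹). Each engineering strategy is encoded as an override
of one parameter's `(c, ΔH_a)` pair — RA steepens V_cmax, PR flattens Γ*,
RUBP scales J_max — so strategies compose freely onto the wild-type set.

Above the leaf, a Beer–Lambert multilayer canopy attenuates light, each
layer's operating electron transport follows a non-rectangular hyperbola,
and a synthetic-weather generator (diurnal + seasonal temperature cycles
around a 21.28°C seasonal mean, half-sinusoid light) drives season
integrations under four climate scenarios: ambient, +5°C, 610 ppm CO2, and
both.

## Worked example

```python
import thermleaf as tl

params = tl.calibrated_parameters()     # wild-type kinetics, calibrated leaf config
env = tl.calibrated_environment()       # 410 ppm, 21% O2, ci/ca = 0.7

curves = {}
for names in ([], ["RA"], ["PR"], ["RA", "PR"]):
    ps = tl.combine(names, params)
    curves[ps.label] = tl.temperature_sweep(ps, env)   # 10–45°C at 0.1°C

print(tl.summary_table(curves, gain_temperatures=(35.0, 40.0)).to_string(index=False))
```

prints

```
strategy   t_opt_c     a_max  gain_vs_wt_35c_pct  gain_vs_wt_40c_pct
      WT 28.140589 17.845603            0.000000            0.000000
      RA 30.907597 19.040567           10.472301           13.912149
      PR 29.275245 18.130869            3.758634            6.545260
   RA+PR 32.435517 19.509912           14.624551           21.367995
```

Read: enhanced rubisco activation moves the thermal optimum up ~2.8°C and
the peak rate up ~7%; the photorespiratory bypass adds ~4% at 35°C and ~7%
at 40°C; stacked, the gains are nearly additive (~15% at 35°C, ~21% at
40°C). The `examples/` directory has one narrative script per capability —
leaf sweeps, strategy stacking, the canopy light gradient, and the
four-scenario season comparison — each printing the numbers it computes and
a line on what they mean.

## Command line

A thin CLI wraps the library for shell use:

```bash
thermleaf sweep --strategies WT,RA,PR --out sweep.csv
thermleaf compare --strategies RA,PR,RA+PR --at 35,40
thermleaf generate-weather --mean-temp 21.28 --days 150 --seed 1 --out weather.csv
thermleaf season --strategies WT,PR,RA+PR --seeds 1..10 --out table.csv
```

Every file output gets a `.manifest.json` sidecar (config hash, seeds,
package version) sufficient to regenerate it. Configuration is plain YAML
(`thermleaf.load_config`); unknown keys are rejected rather than ignored.

## Scope

The canopy and season layers are deliberate simplifications — single-stream
light attenuation, leaf temperature equal to air temperature, no water
balance, no phenology — built to carry the *mechanism* (shaded layers run
RuBP-limited, so Γ*/J_max strategies scale better than V_cmax strategies)
rather than absolute yields. See `docs/methods.md` for the model's
assumptions, parameter choices and limitations.
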