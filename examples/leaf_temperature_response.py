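"""Temperature response of an unmodified C3 leaf.

Sweeps the FvCB model from 10 to 45°C under 410 ppm CO2, 21% O2 and
saturating light, then reports the thermal optimum and where the limiting
process switches between RuBP regeneration (cool end) and rubisco
carboxylation.
"""

import thermleaf as tl

params = tl.calibrated_parameters()
env = tl.calibrated_environment()

curve = tl.temperature_sweep(params, env)  # 10–45°C at 0.1°C
opt = tl.find_optimum(curve)
crossings = tl.limitation_crossover(curve)

print(f"A_N at 25°C : {curve.interp_a_n(25.0):6.2f} µmol m⁻² s⁻¹")
print(f"T_max       : {opt.t_opt:6.2f} °C   (temperature of peak A_N)")
print(f"A_max       : {opt.a_max:6.2f} µmol m⁻² s⁻¹ (peak A_N)")
print(f"crossovers  : {', '.join(f'{t:.2f}°C' for t in crossings)}")
print()
print("Below the crossover the leaf is RuBP-regeneration-limited (electron")
print("transport can't keep up); above it rubisco carboxylation limits, and")
print("A_N falls once Γ* and K_C outgrow V_cmax.")
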