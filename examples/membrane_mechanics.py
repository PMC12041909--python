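"""Actuator-membrane mechanics: profile fits, strain, gap resolution.

Generates deflection profiles linear in pressure, fits them with
even polynomials (order 12), computes the arc-length engineering strain
and the gap-height resolution per 0.1 mbar controller step.
"""

from tconfine.mechanics import arc_strain, fit_profile, pressure_linearity
from tconfine.simulate import gen_deflection_profiles

pressures = [50.0, 100.0, 150.0, 200.0]
profiles = gen_deflection_profiles(slope=6.5, pressures=pressures,
                                   half_width=5.0, noise_sd=5.0, seed=0)

apexes = []
for prof in profiles:
    fit = fit_profile(prof, order=12)
    eps = arc_strain(fit, half_width=5.0)  # z in um, x in mm
    apexes.append(fit.apex)
    print(f"{prof.pressure_mbar:5.0f} mbar: apex {fit.apex:7.1f} um, "
          f"strain {eps:.3%}")

pfit = pressure_linearity(pressures, apexes)
print(f"deflection slope : {pfit.slope:.3f} um/mbar (R^2 = {pfit.r_squared:.5f})")
print(f"gap resolution   : {pfit.resolution:.3f} um per "
      f"{pfit.controller_step} mbar controller step")
# The strain grows with pressure as the membrane bulges; the linear
# apex-pressure relation sets how finely the gap height can be tuned.
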