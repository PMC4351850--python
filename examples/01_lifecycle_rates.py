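"""The closed-form vital rates of the lifecycle model.

Prints the hatch-time curve at its branch boundaries, the age-dependent
adult mortality curve, and the density-dependent larval mortality at a
few biomass loads. No simulation is run; these are the building blocks
every campaign rests on.
"""

import numpy as np

from sitsim import adult_mortality_rate, larval_mortality_rate, sample_hatch_time

print("Hatch time Ht(x) in hours (uniform draw -> development delay):")
for x in (0.0, 0.25, 0.5, 0.501, 0.85, 0.9, 0.94, 1.0):
    print(f"  x = {x:<5} -> {sample_hatch_time(x):7.2f} h")
print("  (note the printed jump at x = 0.5 and the long tail to 240 h)")

print("\nDaily adult mortality by age since emergence:")
for n in (0, 5, 10, 25, 50, 100):
    print(f"  age {n:>3} d -> {adult_mortality_rate(n):.4f}")
print("  (0.1 at emergence, asymptote 0.4: senescence)")

print("\nDaily larval mortality at carrying capacity C = 1000:")
for l_mass in (0, 500, 1000, 2000):
    rates = [larval_mortality_rate(n, l_mass, 1000.0) for n in (1, 5, 10)]
    print(f"  L_mass = {l_mass:>4}: age 1 d {rates[0]:.3f}, age 5 d {rates[1]:.3f}, age 10 d {rates[2]:.3f}")
print("  (crowding raises mortality, and hits young larvae hardest)")
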