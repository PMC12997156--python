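"""Forward NMRD profiles for the two benchmark Cu(II) complexes.

Evaluates the SBM inner-sphere + translational outer-sphere relaxivity
model at the published best-fit parameters and prints the 20 MHz
relaxivities at 298 and 310 K — the numbers usually quoted to compare
contrast-agent candidates.
"""

import numpy as np

from cuprelax import inner_sphere_relaxivity, nmrd_profile, outer_sphere_relaxivity
from cuprelax.presets import CU_TACN, CU_TREN_PH7

for preset in (CU_TACN, CU_TREN_PH7):
    prof = nmrd_profile(preset.inner, preset.outer, [20.0], [298.15, 310.0])
    import math

    from cuprelax.constants import GAMMA_1H

    B20 = 2 * math.pi * 20e6 / GAMMA_1H
    r_is = inner_sphere_relaxivity(preset.inner, B20, 298.15)
    r_os = outer_sphere_relaxivity(preset.outer, preset.inner.tau_S, B20, 298.15)
    print(f"{preset.name}:")
    print(f"  r1(20 MHz, 298 K) = {prof.r1[0]:.3f} mM^-1 s^-1 "
          f"(inner {r_is:.3f} + outer {r_os:.3f})")
    print(f"  r1(20 MHz, 310 K) = {prof.r1[1]:.3f} mM^-1 s^-1")

# The full dispersion profile: a low-field plateau, one dispersion near
# the electron-Larmor condition (a few MHz), and a high-field plateau.
fields = np.geomspace(0.01, 120.0, 25)
prof = nmrd_profile(CU_TACN.inner, CU_TACN.outer, fields, [298.15])
lo, hi = prof.r1[0], prof.r1[-1]
print(f"\nCu(TACN) profile at 298 K: {lo:.3f} at 0.01 MHz -> {hi:.3f} at "
      f"120 MHz (single dispersion, dipolar-dominated)")
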