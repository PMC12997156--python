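"""CW-EPR simulation and tau_R extraction for Cu(TACN).

Simulates the frozen-solution (rigid-limit powder) X-band spectrum and
the room-temperature fast-motion spectrum, then refits the rotational
correlation time from a noisy synthetic room-temperature trace with
tau_R as the single adjustable parameter.
"""

import numpy as np

from cuprelax import SpinSystemCu, fit_tau_R, powder_spectrum
from cuprelax.presets import SPIN_TACN
from cuprelax.synthetic import generate_cw_spectrum

sys = SpinSystemCu(g=SPIN_TACN["g"], A_Cu=SPIN_TACN["A_Cu"])

# rigid limit: axial pattern with g|| > g_perp and a resolved parallel
# copper quartet (|Az| = 482 MHz) at low field
grid = np.linspace(240.0, 380.0, 2000)
rigid = powder_spectrum(sys, 9.42e9, grid, mode="derivative")
peak = grid[np.argmax(rigid.ordinate)]
print(f"rigid-limit derivative extremum at {peak:.1f} mT "
      "(perpendicular ridge; parallel quartet spans the low-field side)")

# fast motion: four mI lines at <g>, widths carry the tau_R information
tau_true = SPIN_TACN["tau_R"]
spec = generate_cw_spectrum(sys, regime="fast_motion", tau_R=tau_true,
                            noise_frac=0.01, seed=7)
tau, err = fit_tau_R(spec, sys)
print(f"tau_R fit: {tau * 1e12:.2f} +/- {err * 1e12:.2f} ps "
      f"(generating value {tau_true * 1e12:.1f} ps)")
print("The mI-dependent Lorentzian widths (motional narrowing) make tau_R "
      "identifiable from a single room-temperature spectrum.")
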