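"""Post-processing utilities: MD rotational correlation time and Evans/BMS
effective magnetic moment.

``fit_autocorrelation_tau`` extracts tau_R from a segment-averaged
rotational autocorrelation trace by a single-exponential fit C(t) =
exp(-t/tau_R) with the amplitude pinned at 1 — the trace is expected to be
normalized, and a deviating C(0) triggers a warning rather than a silent
rescale.

``evans_mu_eff`` converts the bulk-magnetic-susceptibility shift of a
reference resonance into an effective moment, using the SI cylindrical
sample geometry parallel to B0 (superconducting magnet):
chi_M = 3 Df / (4 pi f c') with c' in mol m^-3, then
mu_eff = 797.8 sqrt(chi_M T) Bohr magnetons (CGS-equivalent constant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["AutocorrTrace", "fit_autocorrelation_tau", "evans_mu_eff"]


@dataclass
class AutocorrTrace:
    """Segment-averaged rotational autocorrelation C(t).

    ``lag_ps`` strictly increasing from 0; C(0) must be 1 within noise.
    ``segment_length_ps`` and ``n_segments`` record how the average was
    formed (trajectory split into fixed-length segments).
    """

    lag_ps: np.ndarray
    values: np.ndarray
    segment_length_ps: float = 200.0
    n_segments: int = 1

    def __post_init__(self) -> None:
        self.lag_ps = np.asarray(self.lag_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lag_ps.shape != self.values.shape or self.lag_ps.ndim != 1:
            raise ValueError("lags and values must be equal-length 1-D")
        if not np.all(np.diff(self.lag_ps) > 0):
            raise ValueError("lag times must be strictly increasing")


def fit_autocorrelation_tau(trace: AutocorrTrace) -> tuple[float, float]:
    """Single-exponential tau_R (ps) and 1-sigma uncertainty from C(t).

    The fit window ends at 5 expected tau_R (from a log-slope estimate) or
    the first zero crossing, whichever comes first — long-lag noise
    otherwise dominates.  The amplitude is fixed at 1; a trace whose C(0)
    deviates by more than 5% triggers a normalization warning.
    """
    if len(trace.lag_ps) < 10:
        raise ValueError("need at least 10 lag points")
    if trace.values[0] <= 0:
        raise ValueError("initial autocorrelation value must be positive")
    if abs(trace.values[0] - 1.0) > 0.05:
        warnings.warn(
            f"C(0) = {trace.values[0]:.3f} deviates from 1: trace is not "
            "normalized; amplitude remains pinned at 1",
            stacklevel=2,
        )

    t, c = trace.lag_ps, trace.values
    # crude tau estimate: first drop below 1/e, else last point
    below = np.nonzero(c < math.exp(-1.0))[0]
    tau0 = t[below[0]] if below.size else t[-1]
    zero = np.nonzero(c <= 0)[0]
    t_end = min(5.0 * tau0, t[zero[0]] if zero.size else t[-1])
    win = t <= t_end
    if win.sum() < 5:
        raise ValueError("non-decaying trace: tau_R not identifiable")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat traces trigger scipy warnings
        popt, pcov = curve_fit(
            lambda tt, tau: np.exp(-tt / tau), t[win], c[win], p0=[tau0]
        )
    tau, err = float(popt[0]), float(np.sqrt(pcov[0, 0]))
    if tau <= 0 or not math.isfinite(tau) or tau > 50.0 * t[win][-1]:
        raise ValueError("non-decaying trace: tau_R not identifiable")
    return tau, err


#: Curie constant: mu_eff = 797.8 sqrt(chi_M[SI, m^3/mol] * T)
_EVANS_CONST = 797.8


def evans_mu_eff(
    delta_f: float, spectrometer_f: float, conc: float, T: float
) -> float:
    """Effective magnetic moment (Bohr magnetons) from the BMS shift.

    Parameters
    ----------
    delta_f : frequency shift of the reference resonance, Hz.
    spectrometer_f : proton observe frequency, Hz.
    conc : paramagnetic solute concentration, mol L^-1.
    T : temperature, K.

    SI molar susceptibility for a cylindrical sample parallel to B0:
    chi_M = 3 Df / (4 pi f c) with c in mol m^-3 (giving m^3 mol^-1), then
    the Curie inversion mu_eff = 797.8 sqrt(chi_M T) — the 797.8 constant
    is sqrt(3 kB/(mu0 NA muB^2)) and pairs with chi_M in SI m^3 mol^-1
    (the CGS-equivalent of 2.828 with chi in cm^3 mol^-1).  Diamagnetic
    corrections are off.
    """
    if conc <= 0:
        raise ValueError("concentration must be positive")
    if spectrometer_f <= 0:
        raise ValueError("spectrometer frequency must be positive")
    conc_m3 = conc * 1e3  # mol L^-1 -> mol m^-3
    chi_si = 3.0 * delta_f / (4.0 * math.pi * spectrometer_f * conc_m3)
    if chi_si < 0:
        chi_si = 0.0
    return _EVANS_CONST * math.sqrt(chi_si * T)


def evans_shift_from_mu(
    mu_eff: float, spectrometer_f: float, conc: float, T: float
) -> float:
    """Inverse of :func:`evans_mu_eff`: synthesize the BMS shift (Hz)."""
    chi_si = (mu_eff / _EVANS_CONST) ** 2 / T
    return chi_si * 4.0 * math.pi * spectrometer_f * conc * 1e3 / 3.0
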