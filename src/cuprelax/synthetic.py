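"""Seeded synthetic-data generators with known ground truth.

Stand-ins for the unreleased raw measurements: every generator is a pure
function of (ground truth, grid, seed) wrapping the corresponding forward
model plus Gaussian noise.  Defaults emulate the published study
conditions — NMRD grids spanning 0.01-10 MHz (fast field cycling) and
20-120 MHz (high-field relaxometer) at {283, 298, 310} K, 17O at 11.7 T
over 275-345 K, X-band CW-EPR at 9.42 GHz — with 1% noise, the stated
instrument uncertainty class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import AutocorrTrace
from .epr import SpinSystemCu, Spectrum, fast_motion_spectrum, powder_spectrum
from .nmrd import NMRDProfile, nmrd_profile
from .o17 import O17Dataset, o17_profile
from .presets import RelaxationPreset

__all__ = [
    "default_nmrd_fields",
    "default_nmrd_temps",
    "default_o17_temps",
    "generate_nmrd",
    "generate_o17",
    "generate_cw_spectrum",
    "generate_autocorr",
]


def default_nmrd_fields(n_low: int = 15, n_high: int = 5) -> np.ndarray:
    """Measurement grid in MHz: log-spaced 0.01-10 plus 20-120."""
    low = np.geomspace(0.01, 10.0, n_low)
    high = np.geomspace(20.0, 120.0, n_high)
    return np.concatenate([low, high])


def default_nmrd_temps() -> np.ndarray:
    return np.array([283.0, 298.0, 310.0])


def default_o17_temps(n: int = 10) -> np.ndarray:
    return np.linspace(275.0, 345.0, n)


def generate_nmrd(
    truth: RelaxationPreset,
    fields_MHz=None,
    temps_K=None,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> NMRDProfile:
    """Forward NMRD profile with multiplicative Gaussian noise.

    ``sigma`` is filled with the nominal noise level so fits weight the
    data as generated; ``noise_frac=0`` returns the exact forward model.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    fields = default_nmrd_fields() if fields_MHz is None else np.asarray(fields_MHz)
    temps = default_nmrd_temps() if temps_K is None else np.asarray(temps_K)
    clean = nmrd_profile(truth.inner, truth.outer, fields, temps)
    rng = np.random.default_rng(seed)
    r1 = clean.r1 * (1.0 + noise_frac * rng.standard_normal(len(clean)))
    df = clean.data.copy()
    df["r1_mM_s"] = np.maximum(r1, 0.0)
    # multiplicative noise model: per-point sigma
    df["sigma"] = noise_frac * clean.r1 if noise_frac > 0 else np.nan
    return NMRDProfile(df)


def generate_o17(
    truth: RelaxationPreset,
    temps_K=None,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> O17Dataset:
    """Reduced 17O dataset (both channels) with per-channel Gaussian noise.

    A q = 0 truth yields pure noise around zero — the basic-pH signature of
    suppressed inner-sphere water exchange.
    """
    if truth.o17 is None:
        raise ValueError(f"preset {truth.name!r} has no 17O model")
    temps = default_o17_temps() if temps_K is None else np.asarray(temps_K)
    clean = o17_profile(truth.o17, temps)
    rng = np.random.default_rng(seed)
    scale_r = np.max(np.abs(clean.R2r)) or 1.0
    scale_d = np.max(np.abs(clean.dwr)) or 1.0
    df = clean.data.copy()
    df["R2r_s"] = np.maximum(
        clean.R2r + noise_frac * scale_r * rng.standard_normal(len(clean)), 0.0
    )
    df["dwr_rad_s"] = clean.dwr + noise_frac * scale_d * rng.standard_normal(
        len(clean)
    )
    if noise_frac > 0:
        df["sigma_R2r"] = noise_frac * scale_r
        df["sigma_dwr"] = noise_frac * scale_d
    return O17Dataset(df)


def generate_cw_spectrum(
    sys: SpinSystemCu,
    regime: str = "rigid",
    mw_freq: float = 9.42e9,
    field_grid_mT=None,
    tau_R: float | None = None,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> Spectrum:
    """CW-EPR spectrum (rigid powder or fast-motion) plus additive noise.

    Noise is scaled to the maximum absolute intensity; the field grid
    defaults to a window bracketing all resonances of the system.
    """
    if regime not in ("rigid", "fast_motion"):
        raise ValueError("regime must be 'rigid' or 'fast_motion'")
    if field_grid_mT is None:
        from .constants import H_PLANCK, MU_BOHR

        g_vals = sys.g.principal_values
        centers = H_PLANCK * mw_freq / (g_vals * MU_BOHR) * 1e3
        span = np.max(np.abs(sys.A_Cu.principal_values)) / (
            np.min(g_vals) * MU_BOHR / H_PLANCK / 1e6
        ) * 1e3
        lo, hi = centers.min() - 2.2 * span, centers.max() + 2.2 * span
        field_grid_mT = np.linspace(lo, hi, 2048)
    if regime == "rigid":
        spec = powder_spectrum(sys, mw_freq, field_grid_mT)
    else:
        if tau_R is None:
            raise ValueError("fast_motion regime requires tau_R")
        spec = fast_motion_spectrum(sys, tau_R, mw_freq, field_grid_mT)
    rng = np.random.default_rng(seed)
    scale = np.max(np.abs(spec.ordinate))
    noisy = spec.ordinate + noise_frac * scale * rng.standard_normal(
        len(spec.ordinate)
    )
    meta = dict(spec.metadata, noise_frac=noise_frac, seed=seed)
    return Spectrum(spec.abscissa, noisy, meta)


def generate_autocorr(
    tau_R_ps: float,
    dt_ps: float = 0.2,
    n_lags: int = 500,
    n_segments: int = 20,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> AutocorrTrace:
    """Segment-averaged exp(-t/tau_R) trace with per-segment Gaussian noise.

    Averaging n_segments independent noisy segments shrinks the residual
    noise as 1/sqrt(n_segments), mimicking the averaging of fixed-length
    trajectory windows.
    """
    if dt_ps <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_lags) * dt_ps
    clean = np.exp(-t / tau_R_ps)
    segs = clean[None, :] + noise_frac * rng.standard_normal((n_segments, n_lags))
    avg = segs.mean(axis=0)
    avg[0] = clean[0]  # C(0) is exactly 1 by construction of the estimator
    return AutocorrTrace(
        t, avg, segment_length_ps=n_lags * dt_ps, n_segments=n_segments
    )
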