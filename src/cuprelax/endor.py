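"""Davies ENDOR simulation for weakly coupled protons.

First-order proton ENDOR of an S = 1/2 centre: each proton contributes a
doublet at nu_pm = |nu_n +/- A_eff/2| with the orientation-selective
effective coupling A_eff.  The field position inside the EPR envelope
selects the orientations that contribute (orientation selection), so
spectra recorded across the envelope map out the hyperfine anisotropy.
All couplings considered here satisfy |A| < 2 nu_n, so first order is
adequate and the hyperfine enhancement of RF intensities is neglected.

The point-dipole distance estimate inverts the axial traceless part of a
proton hyperfine tensor: T_parallel = 2 K_dd / r^3 with
K_dd = (mu0/4pi) ge muB gH muN / h ~ 79.1 MHz A^3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .constants import GAMMA_1H, K_DIPOLAR_MHZ_A3
from .epr import SpinSystemCu, _resonance_fields_grid, fibonacci_hemisphere
from .units import PrincipalTensor

__all__ = [
    "ProtonHyperfine",
    "ENDORSpectrum",
    "endor_frequencies",
    "orientation_selection",
    "endor_powder_spectrum",
    "point_dipole_distance",
]


@dataclass(frozen=True)
class ProtonHyperfine:
    """Per-proton hyperfine tensor (MHz) with Euler angles to the g frame."""

    A: PrincipalTensor
    label: str = "water"
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.label not in ("water", "amino", "CH"):
            raise ValueError("label must be water | amino | CH")

    def check_weak_coupling(self, B0_mT: float) -> None:
        """Warn when |A| approaches 2 nu_n at the working field."""
        nu_n = GAMMA_1H * B0_mT * 1e-3 / (2 * math.pi * 1e6)
        a_max = float(np.max(np.abs(self.A.principal_values)))
        if a_max >= 2.0 * nu_n:
            warnings.warn(
                f"|A| = {a_max:.1f} MHz is not weak against 2 nu_n = "
                f"{2 * nu_n:.1f} MHz; first-order frequencies are inaccurate",
                stacklevel=2,
            )


@dataclass
class ENDORSpectrum:
    """RF-swept ENDOR intensity at a fixed field position."""

    rf_MHz: np.ndarray
    intensity: np.ndarray
    field_mT: float
    selection: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rf_MHz = np.asarray(self.rf_MHz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.diff(self.rf_MHz) > 0):
            raise ValueError("RF axis must be strictly increasing")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensities must be non-negative")


def endor_frequencies(A_eff: float, nu_n: float) -> tuple[float, float]:
    """First-order doublet nu_pm = |nu_n +/- A_eff/2| (MHz)."""
    return abs(nu_n + A_eff / 2.0), abs(nu_n - A_eff / 2.0)


def orientation_selection(
    sys: SpinSystemCu,
    B0_mT: float,
    mw_freq: float,
    bandwidth_MHz: float = 50.0,
    n_orientations: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation weights at a field position within the EPR envelope.

    Returns ``(orientations, weights)``: unit vectors on the hemisphere and
    normalized non-negative weights.  Each orientation is weighted by the
    abundance-weighted sum over mI lines of a Gaussian kernel in the offset
    between B0 and the line's resonance field, with kernel width set by the
    excitation bandwidth.  All-zero weights (B0 outside the envelope) are
    flagged with a warning and returned unnormalized.
    """
    orients = fibonacci_hemisphere(n_orientations)
    from .constants import H_PLANCK, MU_BOHR

    # bandwidth (MHz) -> field kernel sigma (mT) at the isotropic g
    sigma_mT = (
        bandwidth_MHz * 1e6 * H_PLANCK / (sys.g_iso * MU_BOHR) * 1e3
        / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    )
    weights = np.zeros(len(orients))
    for abund, scale in sys.isotope_scales():
        fields = _resonance_fields_grid(sys, orients, mw_freq, scale)
        weights += abund * np.exp(
            -0.5 * ((fields - B0_mT) / sigma_mT) ** 2
        ).sum(axis=1)
    total = weights.sum()
    if total <= 1e-12 * len(orients):
        warnings.warn(
            f"B0 = {B0_mT} mT lies outside the EPR envelope: zero weights",
            stacklevel=2,
        )
        return orients, weights
    return orients, weights / total


def _davies_selectivity(A_eff_MHz, hole_width_MHz: float):
    """Suppression of small couplings by the Davies inversion hole.

    eta(A) = A^2/(A^2 + hole^2): couplings well inside the hole (the
    +/-2 MHz matrix region) are suppressed, larger ones pass unchanged.
    """
    a2 = np.asarray(A_eff_MHz, dtype=float) ** 2
    return a2 / (a2 + hole_width_MHz**2)


def endor_powder_spectrum(
    sys: SpinSystemCu,
    protons: list[ProtonHyperfine],
    B0_mT: float,
    mw_freq: float,
    rf_grid_MHz,
    bandwidth_MHz: float = 50.0,
    rf_fwhm_MHz: float = 0.3,
    hole_width_MHz: float = 2.0,
    n_orientations: int = 2000,
) -> ENDORSpectrum:
    """Orientation-selective powder Davies ENDOR spectrum.

    For every selected orientation the electron quantization axis is
    u = g l/|g l|; each proton contributes both branches at
    nu(mS) = |mS A u - nu_n l| with its tensor rotated into the g frame,
    weighted by orientation selection, multiplicity and the Davies
    selectivity factor, and convolved with a Gaussian RF lineshape.
    """
    rf = np.asarray(rf_grid_MHz, dtype=float)
    intensity = np.zeros_like(rf)
    orients, weights = orientation_selection(
        sys, B0_mT, mw_freq, bandwidth_MHz, n_orientations
    )
    sel = {"mean_weight": float(weights.mean()), "B0_mT": B0_mT}
    if weights.sum() == 0 or not protons:
        return ENDORSpectrum(rf, intensity, B0_mT, sel)

    for p in protons:
        p.check_weak_coupling(B0_mT)
    nu_n = GAMMA_1H * B0_mT * 1e-3 / (2 * math.pi * 1e6)  # MHz
    g_pv = sys.g.principal_values
    gl = orients * g_pv
    u = gl / np.linalg.norm(gl, axis=1, keepdims=True)

    active = weights > weights.max() * 1e-6
    dx = rf[1] - rf[0]
    edges = np.concatenate([rf - dx / 2, [rf[-1] + dx / 2]])
    for p in protons:
        A = p.A.as_matrix()
        w_vec = u[active] @ A.T  # (N,3) MHz
        for mS in (+0.5, -0.5):
            vec = mS * w_vec - nu_n * orients[active]
            freq = np.linalg.norm(vec, axis=1)
            a_eff = 2.0 * np.abs(freq - nu_n)
            amp = (
                weights[active]
                * p.multiplicity
                * _davies_selectivity(a_eff, hole_width_MHz)
            )
            hist, _ = np.histogram(freq, bins=edges, weights=amp)
            intensity += hist
    if rf_fwhm_MHz > 0:
        from .epr import _gauss_kernel

        intensity = np.convolve(intensity, _gauss_kernel(dx, rf_fwhm_MHz), "same")
    return ENDORSpectrum(rf, intensity, B0_mT, sel)


def point_dipole_distance(A: PrincipalTensor) -> float:
    """Cu-H distance (Angstrom) from the point-dipole part of a 1H tensor.

    Removes a_iso, takes the largest principal value T of the traceless
    remainder (the parallel component of the ideal axial tensor
    (-T, -T, 2T) with T = K_dd/r^3) and inverts r = (2 K_dd / T_par)^(1/3).
    Approximate for real tensors whose dipolar part is not purely axial.
    """
    traceless = A.principal_values - A.isotropic
    t_par = float(np.max(traceless))
    if t_par <= 0:
        raise ValueError("traceless tensor has no positive principal value")
    return (2.0 * K_DIPOLAR_MHZ_A3 / t_par) ** (1.0 / 3.0)


def dipolar_tensor_from_distance(r_angstrom: float) -> PrincipalTensor:
    """Forward construction: ideal axial dipolar tensor (-T, -T, 2T), MHz."""
    if r_angstrom <= 0:
        raise ValueError("distance must be positive")
    t = K_DIPOLAR_MHZ_A3 / r_angstrom**3
    return PrincipalTensor(-t, -t, 2.0 * t)
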