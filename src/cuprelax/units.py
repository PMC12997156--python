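"""Tensor containers, scalar reductions and unit conversions.

The ``PrincipalTensor`` holds the three principal values of a g- or
hyperfine tensor together with the Euler angles (ZYZ, degrees) that rotate
its principal frame into the g-tensor frame.  All reductions here are
frame-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import G_ELECTRON, H_PLANCK, MU_BOHR, NucleusSpec

__all__ = [
    "PrincipalTensor",
    "isotropic_average",
    "rad_per_s_to_MHz",
    "MHz_to_rad_per_s",
    "larmor_frequency",
    "resonance_field_isotropic",
]


@dataclass(frozen=True)
class PrincipalTensor:
    """Principal values of a symmetric interaction tensor.

    ``x, y, z`` are in MHz for hyperfine tensors and dimensionless for
    g-tensors.  ``euler_alpha/beta/gamma`` (degrees, ZYZ active convention)
    rotate the tensor's principal frame into the g-tensor frame; they
    default to 0 (coaxial tensors).
    """

    x: float
    y: float
    z: float
    euler_alpha: float = 0.0
    euler_beta: float = 0.0
    euler_gamma: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError("tensor principal values must be finite")
        for a in (self.euler_alpha, self.euler_beta, self.euler_gamma):
            if not -180.0 <= a <= 180.0:
                raise ValueError("Euler angles must lie in [-180, 180] deg")

    @property
    def principal_values(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def isotropic(self) -> float:
        return (self.x + self.y + self.z) / 3.0

    def rotation_matrix(self) -> np.ndarray:
        """Active ZYZ rotation R(alpha, beta, gamma) from principal to g frame."""
        a, b, g = np.deg2rad(
            [self.euler_alpha, self.euler_beta, self.euler_gamma]
        )

        def rz(t):
            c, s = np.cos(t), np.sin(t)
            return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

        def ry(t):
            c, s = np.cos(t), np.sin(t)
            return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

        return rz(a) @ ry(b) @ rz(g)

    def as_matrix(self) -> np.ndarray:
        """3x3 tensor in the g frame: R diag(x, y, z) R^T."""
        rot = self.rotation_matrix()
        return rot @ np.diag(self.principal_values) @ rot.T


def isotropic_average(t: PrincipalTensor) -> float:
    """Isotropic part of a tensor: the arithmetic mean of its principal values.

    For a hyperfine tensor this is a_iso (MHz); for a g-tensor, <g>_av.
    """
    return t.isotropic


def rad_per_s_to_MHz(a: float) -> float:
    """Convert a scalar coupling from angular frequency (rad s^-1) to MHz."""
    return a / (2.0 * math.pi * 1e6)


def MHz_to_rad_per_s(nu: float) -> float:
    """Inverse of :func:`rad_per_s_to_MHz`."""
    return nu * 2.0 * math.pi * 1e6


def larmor_frequency(nucleus: NucleusSpec, field: float) -> float:
    """Nuclear Larmor frequency |gamma| B0 / 2pi in MHz for a field in tesla."""
    if field < 0:
        raise ValueError("field must be non-negative")
    return abs(nucleus.gyromagnetic_ratio) * field / (2.0 * math.pi * 1e6)


def resonance_field_isotropic(g: float, mw_frequency: float) -> float:
    """Electron resonance field h nu / (g muB) in tesla.

    ``mw_frequency`` in Hz.  Sanity anchor for the EPR simulators: for an
    isotropic g the whole powder pattern collapses onto this field.
    """
    if g <= 0 or mw_frequency <= 0:
        raise ValueError("g and mw_frequency must be positive")
    return H_PLANCK * mw_frequency / (g * MU_BOHR)


def electron_larmor_angular(field: float, g: float = G_ELECTRON) -> float:
    """Electron angular Larmor frequency g muB B / hbar (rad s^-1)."""
    from .constants import HBAR

    return g * MU_BOHR * field / HBAR
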