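"""Forward model for the 1H relaxivity of an S = 1/2 Cu(II) complex.

Inner-sphere relaxivity follows Solomon-Bloembergen-Morgan (SBM) theory —
dipolar plus scalar bound-proton relaxation, exchange-limited through the
residence lifetime tau_M — and the outer-sphere term follows the
translational force-free diffusion (Freed) model.  The Curie contribution
is omitted: for S = 1/2 it is far below the dipolar term at every field
considered here.

Temperature laws
----------------
Exchange lifetimes follow Eyring transition-state kinetics,

    k_ex(T) = (kB T / h) exp(dS/R - dH/(R T)),   tau_M = 1/k_ex,

while the rotational correlation time and the relative diffusion
coefficient follow Arrhenius laws referenced to 298.15 K.

All relaxivities are per millimolar of complex (mM^-1 s^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    G_ELECTRON,
    GAMMA_1H,
    H_PLANCK,
    HBAR,
    K_BOLTZMANN,
    MU0_OVER_4PI,
    MU_BOHR,
    N_AVOGADRO,
    R_GAS,
    S_ELECTRON,
    T_REF,
    WATER_MOLARITY,
)

__all__ = [
    "InnerSphereParams",
    "OuterSphereParams",
    "NMRDProfile",
    "tau_eyring",
    "tau_arrhenius",
    "dipolar_rate",
    "scalar_rate",
    "inner_sphere_relaxivity",
    "outer_sphere_relaxivity",
    "nmrd_profile",
]

_SS1 = S_ELECTRON * (S_ELECTRON + 1.0)


def tau_eyring(
    T: float,
    *,
    dH: float | None = None,
    dS: float | None = None,
    tau_298: float | None = None,
) -> float:
    """Exchange lifetime 1/k_ex from Eyring transition-state theory.

    Supply either the activation pair ``(dH, dS)`` (J mol^-1, J mol^-1 K^-1)
    or ``tau_298`` (s); with only ``tau_298`` and ``dH``, the entropy is
    implied by the 298.15 K anchor.  Valid for T in [200, 400] K.
    """
    if not 200.0 <= T <= 400.0:
        raise ValueError(f"temperature {T} K outside the supported 200-400 K")
    if dH is not None and dS is not None:
        k = (K_BOLTZMANN * T / H_PLANCK) * math.exp(dS / R_GAS - dH / (R_GAS * T))
        return 1.0 / k
    if tau_298 is not None:
        if dH is None:
            # no enthalpy: flat 1/k law anchored at 298 (kB T/h prefactor only)
            dH = 0.0
        k298 = 1.0 / tau_298
        dS_implied = R_GAS * math.log(
            k298 * H_PLANCK / (K_BOLTZMANN * T_REF)
        ) + dH / T_REF
        k = (K_BOLTZMANN * T / H_PLANCK) * math.exp(
            dS_implied / R_GAS - dH / (R_GAS * T)
        )
        return 1.0 / k
    raise ValueError("supply (dH, dS) or tau_298")


def tau_arrhenius(tau_298: float, E: float, T: float) -> float:
    """tau(T) = tau_298 exp[(E/R)(1/T - 1/298.15)] (E in J mol^-1)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return tau_298 * math.exp((E / R_GAS) * (1.0 / T - 1.0 / T_REF))


@dataclass(frozen=True)
class InnerSphereParams:
    """Inner-sphere SBM parameters.

    ``q`` counts bound water molecules by default; with
    ``q_is_protons=True`` it counts exchangeable protons instead (the
    hydroxo-complex case, where a single OH proton relaxes via prototropic
    exchange).  ``A_H`` is the proton scalar coupling A_H/hbar in rad s^-1.
    When both ``tau_M_298`` and the Eyring pair are given they must agree
    within 5%; the Eyring pair then defines the temperature dependence.
    """

    q: float
    r_MH: float                      # metal-proton distance, Angstrom
    A_H: float                       # rad s^-1
    tau_S: float                     # electronic relaxation time, s
    tau_R_298: float                 # rotational correlation time at 298 K, s
    E_R: float                       # Arrhenius energy of tau_R, J mol^-1
    tau_M_298: float | None = None   # residence lifetime at 298 K, s
    dH_M: float | None = None        # J mol^-1
    dS_M: float | None = None        # J mol^-1 K^-1
    q_is_protons: bool = False

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.r_MH <= 0:
            raise ValueError("r_MH must be positive")
        for name in ("tau_S", "tau_R_298"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_M_298 is None and (self.dH_M is None or self.dS_M is None):
            raise ValueError("supply tau_M_298 or the Eyring pair (dH_M, dS_M)")
        if (
            self.tau_M_298 is not None
            and self.dH_M is not None
            and self.dS_M is not None
        ):
            implied = tau_eyring(T_REF, dH=self.dH_M, dS=self.dS_M)
            if abs(implied - self.tau_M_298) / self.tau_M_298 > 0.05:
                raise ValueError(
                    f"tau_M_298={self.tau_M_298:.3g} s disagrees with the "
                    f"Eyring pair (implies {implied:.3g} s) by more than 5%"
                )

    def tau_M(self, T: float) -> float:
        """Residence lifetime at temperature T (Eyring if available)."""
        if self.dH_M is not None and self.dS_M is not None:
            return tau_eyring(T, dH=self.dH_M, dS=self.dS_M)
        return tau_eyring(T, tau_298=self.tau_M_298)

    def tau_R(self, T: float) -> float:
        return tau_arrhenius(self.tau_R_298, self.E_R, T)


@dataclass(frozen=True)
class OuterSphereParams:
    """Translational (Freed) outer-sphere parameters.

    ``a`` is the distance of closest approach (Angstrom), ``D_298`` the
    relative solute-water diffusion coefficient at 298.15 K (m^2 s^-1) and
    ``E_D`` its Arrhenius activation energy (J mol^-1).
    """

    a: float = 3.6
    D_298: float = 2.3e-9
    E_D: float = 20.0e3

    def __post_init__(self) -> None:
        if self.a <= 0 or self.D_298 <= 0:
            raise ValueError("a and D_298 must be positive")

    def D(self, T: float) -> float:
        # diffusion speeds up with temperature: negate E in the tau law
        return tau_arrhenius(self.D_298, -self.E_D, T)


@dataclass
class NMRDProfile:
    """Relaxivity observations on a (frequency, temperature) grid.

    Stored as a DataFrame with columns ``freq_MHz, temp_K, r1_mM_s, sigma``;
    rows are sorted by (temperature, frequency) on construction.
    """

    data: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    COLUMNS = ("freq_MHz", "temp_K", "r1_mM_s", "sigma")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        if "sigma" not in df.columns:
            df["sigma"] = np.nan
        df = df[list(self.COLUMNS)]
        if (df["freq_MHz"] <= 0).any():
            raise ValueError("proton frequencies must be positive")
        if (df["r1_mM_s"] < 0).any():
            raise ValueError("relaxivities must be non-negative")
        self.data = df.sort_values(["temp_K", "freq_MHz"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def freq_MHz(self) -> np.ndarray:
        return self.data["freq_MHz"].to_numpy()

    @property
    def temp_K(self) -> np.ndarray:
        return self.data["temp_K"].to_numpy()

    @property
    def r1(self) -> np.ndarray:
        return self.data["r1_mM_s"].to_numpy()

    @property
    def sigma(self) -> np.ndarray:
        return self.data["sigma"].to_numpy()


def _field_from_proton_MHz(nu_MHz):
    return 2.0 * math.pi * np.asarray(nu_MHz, dtype=float) * 1e6 / GAMMA_1H


def dipolar_rate(p: InnerSphereParams, B0, T: float):
    """Bound-proton dipolar relaxation rate 1/T1M^DD (s^-1).

    (2/15)(mu0/4pi)^2 gammaH^2 ge^2 muB^2 S(S+1) r^-6
        [3 tau_c/(1+wH^2 tau_c^2) + 7 tau_c/(1+wS^2 tau_c^2)],
    1/tau_c = 1/tau_R(T) + 1/tau_M(T) + 1/tau_S.
    """
    B0 = np.asarray(B0, dtype=float)
    if np.any(B0 <= 0):
        raise ValueError("B0 must be positive")
    r_m = p.r_MH * 1e-10
    wH = GAMMA_1H * B0
    wS = G_ELECTRON * MU_BOHR * B0 / HBAR
    tc = 1.0 / (1.0 / p.tau_R(T) + 1.0 / p.tau_M(T) + 1.0 / p.tau_S)
    pref = (
        (2.0 / 15.0)
        * MU0_OVER_4PI**2
        * GAMMA_1H**2
        * (G_ELECTRON * MU_BOHR) ** 2
        * _SS1
        / r_m**6
    )
    return pref * (
        3.0 * tc / (1.0 + wH**2 * tc**2) + 7.0 * tc / (1.0 + wS**2 * tc**2)
    )


def scalar_rate(p: InnerSphereParams, B0, T: float):
    """Bound-proton scalar (contact) rate 1/T1M^SC (s^-1).

    (2/3) S(S+1) (A_H/hbar)^2 tau_e2/(1+wS^2 tau_e2^2),
    1/tau_e2 = 1/tau_M(T) + 1/tau_S.
    """
    B0 = np.asarray(B0, dtype=float)
    wS = G_ELECTRON * MU_BOHR * B0 / HBAR
    te2 = 1.0 / (1.0 / p.tau_M(T) + 1.0 / p.tau_S)
    return (2.0 / 3.0) * _SS1 * p.A_H**2 * te2 / (1.0 + wS**2 * te2**2)


def inner_sphere_relaxivity(p: InnerSphereParams, B0, T: float):
    """Inner-sphere relaxivity (mM^-1 s^-1).

    r1IS = x_m / (T1M + tau_M) with the per-mM bound mole fraction
    x_m = q/55560 for q water molecules (two protons each, matching the
    55.56 M proton-pair normalization) or q/111120 for q single protons.
    """
    rate = dipolar_rate(p, B0, T) + scalar_rate(p, B0, T)
    T1M = 1.0 / rate
    per_site = 2.0 if p.q_is_protons else 1.0
    frac = p.q * 1e-3 / (per_site * WATER_MOLARITY)
    return frac / (T1M + p.tau_M(T))


def _freed_J(omega, tau_D: float, tau_S: float):
    """Freed spectral density Re[(1+z/4)/(1+z+4z^2/9+z^3/9)], J(0)->1."""
    z = np.sqrt(1j * np.asarray(omega, dtype=float) * tau_D + tau_D / tau_S)
    return np.real((1.0 + z / 4.0) / (1.0 + z + 4.0 * z**2 / 9.0 + z**3 / 9.0))


def outer_sphere_relaxivity(
    os: OuterSphereParams, tau_S: float, B0, T: float, conc_mM: float = 1.0
):
    """Outer-sphere (translational diffusion) relaxivity per mM (mM^-1 s^-1).

    (32pi/405)(mu0/4pi)^2 gammaH^2 (ge muB/hbar)^2 hbar^2 S(S+1)
        N_A [C] / (a D) * [3 J(wH) + 7 J(wS)],

    with the translational correlation time tau_D = 2 a^2 / D(T) entering
    the spectral-density argument z = sqrt(i w tau_D + tau_D/tau_S).  The
    2a^2/D convention is the one under which this model, combined with the
    inner-sphere term, reproduces the fitted relaxivities of the systems
    this package targets (see docs/methods.md for the convention note).
    """
    B0 = np.asarray(B0, dtype=float)
    a_m = os.a * 1e-10
    D = os.D(T)
    tau_D = 2.0 * a_m**2 / D
    wH = GAMMA_1H * B0
    wS = G_ELECTRON * MU_BOHR * B0 / HBAR
    conc = conc_mM  # 1 mM = 1 mol m^-3
    pref = (
        (32.0 * math.pi / 405.0)
        * MU0_OVER_4PI**2
        * GAMMA_1H**2
        * (G_ELECTRON * MU_BOHR / HBAR) ** 2
        * HBAR**2
        * _SS1
        * N_AVOGADRO
        * conc
        / (a_m * D)
    )
    return pref * (
        3.0 * _freed_J(wH, tau_D, tau_S) + 7.0 * _freed_J(wS, tau_D, tau_S)
    )


def nmrd_profile(
    p: InnerSphereParams,
    os: OuterSphereParams,
    fields_MHz: Sequence[float],
    temps_K: Sequence[float],
    os_conc_mM: float = 1.0,
) -> NMRDProfile:
    """Full NMRD profile r1(nu, T) = r1IS + r1OS over a (field x temp) grid.

    ``os_conc_mM`` scales the outer-sphere term (0 disables it entirely).
    """
    fields_MHz = np.asarray(fields_MHz, dtype=float)
    temps_K = np.asarray(temps_K, dtype=float)
    if fields_MHz.size == 0 or temps_K.size == 0:
        raise ValueError("field and temperature grids must be non-empty")
    rows = []
    for T in temps_K:
        B0 = _field_from_proton_MHz(fields_MHz)
        r1 = inner_sphere_relaxivity(p, B0, T) + outer_sphere_relaxivity(
            os, p.tau_S, B0, T, conc_mM=os_conc_mM
        )
        for nu, val in zip(fields_MHz, np.atleast_1d(r1)):
            rows.append((nu, T, val, np.nan))
    return NMRDProfile(pd.DataFrame(rows, columns=list(NMRDProfile.COLUMNS)))
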