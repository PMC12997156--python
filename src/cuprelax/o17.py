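"""Swift-Connick model for variable-temperature 17O NMR of bound water.

The observable quantities are the reduced transverse relaxation rate and
reduced chemical shift of the bulk-water 17O resonance — "reduced" meaning
normalized by the bound-water mole fraction, so both are intensive,
concentration-free properties of the exchange process.

Bound-site transverse relaxation is taken as purely scalar, the dominant
mechanism for 17O bound to a paramagnetic centre; the bound-site contact
shift follows the Curie-type form Dw_M = ge muB S(S+1) B0/(3 kB T) A_O/hbar.
Outer-sphere 17O contributions are neglected (they are flat and tiny next
to the exchange-driven terms; a q = 0 configuration yields a zero dataset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .constants import (
    G_ELECTRON,
    HBAR,
    K_BOLTZMANN,
    MU_BOHR,
    S_ELECTRON,
)
from .nmrd import tau_eyring

__all__ = [
    "O17Params",
    "O17Dataset",
    "delta_omega_M",
    "t2m_scalar",
    "swift_connick_reduced",
    "o17_profile",
]

_SS1 = S_ELECTRON * (S_ELECTRON + 1.0)

#: default measurement field (T)
B0_DEFAULT = 11.7


@dataclass(frozen=True)
class O17Params:
    """Parameters of the bound-water 17O exchange model.

    ``A_O`` is the 17O scalar coupling A_O/hbar in rad s^-1; the exchange
    lifetime shares the Eyring parametrization with the proton model.
    """

    A_O: float
    q: float
    tau_S: float
    dH_M: float | None = None
    dS_M: float | None = None
    tau_M_298: float | None = None
    B0: float = B0_DEFAULT

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if self.tau_M_298 is None and (self.dH_M is None or self.dS_M is None):
            raise ValueError("supply tau_M_298 or the Eyring pair (dH_M, dS_M)")

    def tau_M(self, T: float) -> float:
        if self.dH_M is not None and self.dS_M is not None:
            return tau_eyring(T, dH=self.dH_M, dS=self.dS_M)
        return tau_eyring(T, tau_298=self.tau_M_298)


@dataclass
class O17Dataset:
    """Reduced 17O observations vs temperature.

    Columns: ``temp_K, R2r_s, dwr_rad_s, sigma_R2r, sigma_dwr``.
    Temperatures must be strictly increasing; R2r >= 0.
    """

    data: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    COLUMNS = ("temp_K", "R2r_s", "dwr_rad_s", "sigma_R2r", "sigma_dwr")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        for col in ("sigma_R2r", "sigma_dwr"):
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(self.COLUMNS)].reset_index(drop=True)
        t = df["temp_K"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if (df["R2r_s"] < 0).any():
            raise ValueError("reduced rates must be non-negative")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def temp_K(self) -> np.ndarray:
        return self.data["temp_K"].to_numpy()

    @property
    def R2r(self) -> np.ndarray:
        return self.data["R2r_s"].to_numpy()

    @property
    def dwr(self) -> np.ndarray:
        return self.data["dwr_rad_s"].to_numpy()


def delta_omega_M(A_O: float, B0: float, T: float) -> float:
    """Bound-water 17O contact shift Dw_M (rad s^-1).

    Dw_M = ge muB S(S+1) B0 / (3 kB T) * (A_O/hbar).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return G_ELECTRON * MU_BOHR * _SS1 * B0 / (3.0 * K_BOLTZMANN * T) * A_O


def t2m_scalar(A_O: float, tau_M: float, tau_S: float, B0: float) -> float:
    """Bound-site scalar transverse rate 1/T2M (s^-1).

    (S(S+1)/3)(A_O/hbar)^2 [tau_e1 + tau_e2/(1+wS^2 tau_e2^2)] with a single
    electronic time: 1/tau_e = 1/tau_M + 1/tau_S.
    """
    if tau_M <= 0 or tau_S <= 0:
        raise ValueError("lifetimes must be positive")
    te = 1.0 / (1.0 / tau_M + 1.0 / tau_S)
    wS = G_ELECTRON * MU_BOHR * B0 / HBAR
    return (_SS1 / 3.0) * A_O**2 * (te + te / (1.0 + wS**2 * te**2))


def swift_connick_reduced(p: O17Params, T: float) -> tuple[float, float]:
    """Reduced transverse rate and shift (R2r in s^-1, dw_r in rad s^-1).

    Swift-Connick exchange expressions evaluated with the Eyring tau_M(T):

        R2r = (1/tau_M) [T2M^-2 + (T2M tau_M)^-1 + Dw_M^2]
                        / [(T2M^-1 + tau_M^-1)^2 + Dw_M^2]
        dw_r = Dw_M / [(1 + tau_M/T2M)^2 + tau_M^2 Dw_M^2]

    A q = 0 configuration (no bound water in exchange) returns zeros.
    """
    if p.q == 0:
        return 0.0, 0.0
    tau_M = p.tau_M(T)
    if tau_M <= 0:
        raise ValueError("tau_M must be positive")
    inv_T2M = t2m_scalar(p.A_O, tau_M, p.tau_S, p.B0)
    dwM = delta_omega_M(p.A_O, p.B0, T)
    num = inv_T2M**2 + inv_T2M / tau_M + dwM**2
    den = (inv_T2M + 1.0 / tau_M) ** 2 + dwM**2
    R2r = (1.0 / tau_M) * num / den
    dwr = dwM / ((1.0 + tau_M * inv_T2M) ** 2 + tau_M**2 * dwM**2)
    return R2r, dwr


def o17_profile(p: O17Params, temps_K) -> O17Dataset:
    """Apply :func:`swift_connick_reduced` over a temperature grid."""
    temps_K = np.sort(np.asarray(temps_K, dtype=float))
    if temps_K.size == 0:
        raise ValueError("temperature grid must be non-empty")
    rows = [(T, *swift_connick_reduced(p, T), math.nan, math.nan) for T in temps_K]
    return O17Dataset(pd.DataFrame(rows, columns=list(O17Dataset.COLUMNS)))
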