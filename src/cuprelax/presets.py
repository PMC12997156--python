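"""Published parameter sets for the two benchmark Cu(II) complexes.

[Cu(TACN)]2+ (square-pyramidal, q = 2, fast water exchange) and
[Cu(TREN)]2+ (trigonal-bipyramidal, q = 1, slow exchange; at pH 12 the
hydroxo complex with prototropic proton exchange).  These presets seed the
synthetic-data generators and serve as fit starting points; each value
carries its experimental provenance in the comments.

Hyperfine signs follow the DFT-determined convention; magnitudes are used
wherever an observable is sign-blind.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nmrd import InnerSphereParams, OuterSphereParams
from .o17 import O17Params
from .units import PrincipalTensor

__all__ = [
    "RelaxationPreset",
    "CU_TACN",
    "CU_TREN_PH7",
    "CU_TREN_PH12",
    "SPIN_TACN",
    "SPIN_TREN",
    "SPIN_TACN_DFT",
    "SPIN_TREN_DFT",
    "PROTONS_TACN",
    "PROTONS_TREN",
    "TAU_R_EPR",
]


@dataclass(frozen=True)
class RelaxationPreset:
    """Bundle of inner/outer-sphere and 17O parameters for one complex."""

    name: str
    inner: InnerSphereParams
    outer: OuterSphereParams
    o17: O17Params | None
    OH_conc: float = 0.0  # mol L^-1, nonzero only for the prototropic case


# --- relaxometric fit parameters (NMRD + 17O joint analysis) ---

CU_TACN = RelaxationPreset(
    name="Cu(TACN) pH 4.5",
    inner=InnerSphereParams(
        q=2,                      # two inner-sphere waters
        r_MH=2.56,                # A, ENDOR/DFT water-proton distance
        A_H=8.3e6,                # rad s^-1 (1.3 MHz)
        tau_S=0.98e-9,            # s
        tau_R_298=10.6e-12,       # s
        E_R=20.2e3,               # J mol^-1
        dH_M=9.0e3,               # J mol^-1  -> tau_M(298) = 75 ps
        dS_M=-20.9,               # J mol^-1 K^-1
    ),
    outer=OuterSphereParams(a=3.6, D_298=2.3e-9, E_D=20.0e3),
    o17=O17Params(A_O=2.82e8, q=2, tau_S=0.98e-9, dH_M=9.0e3, dS_M=-20.9),
)

CU_TREN_PH7 = RelaxationPreset(
    name="Cu(TREN) pH 7.4",
    inner=InnerSphereParams(
        q=1,
        r_MH=2.48,
        A_H=3.8e6,                # rad s^-1 (0.61 MHz)
        tau_S=0.54e-9,
        tau_R_298=10e-12,
        E_R=18.1e3,
        dH_M=40.0e3,              # -> tau_M(298) = 245 ns (reported 253 +/- 15)
        dS_M=15.8,
    ),
    outer=OuterSphereParams(a=3.6, D_298=2.3e-9, E_D=20.0e3),
    o17=O17Params(A_O=2.0e8, q=1, tau_S=0.54e-9, dH_M=40.0e3, dS_M=15.8),
)

# pH 12: hydroxo complex.  q counts protons (the single OH proton); the
# Eyring pair parametrizes the OBSERVED effective lifetime tau_M, and the
# elementary proton lifetime follows from the base-catalysed prototropic
# law tau_M(H) = tau_M * [OH-].
CU_TREN_PH12 = RelaxationPreset(
    name="Cu(TREN) pH 12.0",
    inner=InnerSphereParams(
        q=1,
        q_is_protons=True,
        r_MH=2.40,                # A, DFT distance to the hydroxide proton
        A_H=21.04e6,              # rad s^-1 (3.39 MHz)
        tau_S=1.13e-9,
        tau_R_298=10.4e-12,
        E_R=17.9e3,
        dH_M=56.2e3,              # parametrizes the observed tau_M: ~154 ns
        dS_M=74.0,
    ),
    outer=OuterSphereParams(a=3.6, D_298=2.3e-9, E_D=20.0e3),
    o17=None,                     # no 17O exchange observed at basic pH
    OH_conc=1e-2,                 # mol L^-1 at pH 12
)


# --- CW-EPR spin-Hamiltonian parameters (X-band simulations) ---
# hyperfine in MHz, referenced to 63Cu; linewidths chosen to reproduce the
# partially resolved rigid-limit patterns (residual widths are a package
# choice, see docs/methods.md).

SPIN_TACN = {
    "g": PrincipalTensor(2.058, 2.058, 2.288),
    "A_Cu": PrincipalTensor(30.0, 30.0, -482.0),
    "tau_R": 7.6e-12,            # s, from the room-temperature simulation
}

SPIN_TREN = {
    "g": PrincipalTensor(2.191, 2.207, 2.005),
    "A_Cu": PrincipalTensor(-346.0, -332.0, 180.0),
    "tau_R": 13e-12,
}

# DFT counterparts (used only for tensor-reduction checks)
SPIN_TACN_DFT = {
    "g": PrincipalTensor(2.067, 2.077, 2.249),
    "A_Cu": PrincipalTensor(33.0, 60.0, -529.0),
}

SPIN_TREN_DFT = {
    "g": PrincipalTensor(2.182, 2.218, 2.005),
    "A_Cu": PrincipalTensor(-335.0, -222.0, 256.0),
}

#: EPR-derived rotational correlation times (s)
TAU_R_EPR = {"Cu(TACN)": 7.6e-12, "Cu(TREN)": 13e-12}


# --- Q-band ENDOR proton hyperfine tensors (SIM rows; MHz, deg) ---

PROTONS_TACN = [
    # water protons of the two bound H2O; r_Cu-H 2.59 / 2.61 A
    {
        "label": "water",
        "A": PrincipalTensor(-2.80, 8.75, -8.5, 47.3, 47.3, -18.4),
        "multiplicity": 2,
        "r_CuH": 2.59,
    },
    {
        "label": "water",
        "A": PrincipalTensor(9.5, -1.95, -7.5, -162.5, 9.8, -154.5),
        "multiplicity": 2,
        "r_CuH": 2.61,
    },
]

PROTONS_TREN = [
    {
        "label": "water",
        "A": PrincipalTensor(-5.2, -11.8, 5.7, 4.3, 44.7, -1.3),
        "multiplicity": 2,
        "r_CuH": 2.61,
    },
]
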