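"""Physical constants (CODATA 2018) and nuclear data.

Single authoritative table: every other module imports from here and no
physical constant literal appears elsewhere in the package.

Internal unit system: SI throughout — fields in tesla, frequencies in Hz,
angular frequencies in rad s^-1, energies in J mol^-1 where thermodynamic.
Millitesla and MHz appear only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# --- CODATA 2018 fundamental constants (SI) ---
H_PLANCK = 6.62607015e-34        # J s (exact)
HBAR = 1.054571817e-34           # J s
K_BOLTZMANN = 1.380649e-23       # J K^-1 (exact)
N_AVOGADRO = 6.02214076e23       # mol^-1 (exact)
R_GAS = 8.31446261815324         # J mol^-1 K^-1 (exact)
MU_BOHR = 9.2740100783e-24       # J T^-1
MU_NUCLEAR = 5.0507837461e-27    # J T^-1
MU0_OVER_4PI = 1.0e-7            # T m A^-1 (SI redefinition: to 1e-10 relative)
G_ELECTRON = 2.00231930436256    # free-electron g-factor (positive convention)

# --- gyromagnetic ratios, rad s^-1 T^-1 ---
GAMMA_1H = 2.6752218744e8
GAMMA_17O = -3.62808e7
# 63Cu/65Cu from nuclear magnetic moments mu/mu_N = 2.2233 / 2.3817, I = 3/2
GAMMA_63CU = 2.2233 * MU_NUCLEAR / (1.5 * HBAR)
GAMMA_65CU = 2.3817 * MU_NUCLEAR / (1.5 * HBAR)
#: hyperfine scaling 65Cu/63Cu (ratio of gyromagnetic ratios, ~1.0713)
CU65_OVER_CU63 = GAMMA_65CU / GAMMA_63CU

G_PROTON = 5.5856946893          # proton nuclear g-factor

T_REF = 298.15                   # K, reference temperature for tau(298) laws
WATER_MOLARITY = 55.56           # mol L^-1, pure water at 298 K
S_ELECTRON = 0.5                 # electron spin of Cu(II), d9

#: point-dipole constant (mu0/4pi) ge muB gH muN / h, in MHz Angstrom^3 (~79.1)
K_DIPOLAR_MHZ_A3 = (
    MU0_OVER_4PI * G_ELECTRON * MU_BOHR * G_PROTON * MU_NUCLEAR / H_PLANCK
) * 1e24  # m^3 Hz -> MHz A^3


@dataclass(frozen=True)
class NucleusSpec:
    """An NMR/EPR-active nucleus.

    Parameters
    ----------
    name : text label, e.g. ``"1H"`` or ``"63Cu"``.
    spin : nuclear spin quantum number (half-integer).
    gyromagnetic_ratio : rad s^-1 T^-1 (signed).
    natural_abundance : isotopic fraction in [0, 1].
    """

    name: str
    spin: float
    gyromagnetic_ratio: float
    natural_abundance: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.gyromagnetic_ratio):
            raise ValueError(f"non-finite gyromagnetic ratio for {self.name}")
        if not 0.0 <= self.natural_abundance <= 1.0:
            raise ValueError(
                f"abundance of {self.name} must lie in [0, 1], "
                f"got {self.natural_abundance}"
            )
        if self.spin < 0 or round(2 * self.spin) != 2 * self.spin:
            raise ValueError(f"spin of {self.name} must be a half-integer >= 0")


PROTON = NucleusSpec("1H", 0.5, GAMMA_1H, 0.999885)
O17 = NucleusSpec("17O", 2.5, GAMMA_17O, 3.8e-4)
CU63 = NucleusSpec("63Cu", 1.5, GAMMA_63CU, 0.6917)
CU65 = NucleusSpec("65Cu", 1.5, GAMMA_65CU, 0.3083)

#: natural copper isotope pair; abundances sum to 1 within 1e-9
CU_ISOTOPES = (CU63, CU65)


def check_isotope_set(isotopes) -> None:
    """Validate that the abundances of an isotope set sum to 1 (tol 1e-9)."""
    total = sum(n.natural_abundance for n in isotopes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"isotope abundances sum to {total!r}, expected 1")
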