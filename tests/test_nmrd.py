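"""SBM inner-sphere, Freed outer-sphere and temperature-law tests."""

import math

import numpy as np
import pytest

from cuprelax import (
    InnerSphereParams,
    OuterSphereParams,
    dipolar_rate,
    inner_sphere_relaxivity,
    nmrd_profile,
    outer_sphere_relaxivity,
    scalar_rate,
    tau_arrhenius,
    tau_eyring,
)
from cuprelax.constants import (
    G_ELECTRON,
    GAMMA_1H,
    HBAR,
    K_BOLTZMANN,
    H_PLANCK,
    MU0_OVER_4PI,
    MU_BOHR,
    R_GAS,
)
from cuprelax.presets import CU_TACN, CU_TREN_PH7

B20 = 2 * math.pi * 20e6 / GAMMA_1H  # 20 MHz proton frequency in tesla


class TestTemperatureLaws:
    def test_eyring_fast_exchanger(self):
        # dH = 9.0 kJ/mol, dS = -20.9 J/mol/K -> 75 ps at 298.15 K
        assert tau_eyring(298.15, dH=9.0e3, dS=-20.9) == pytest.approx(
            0.075e-9, rel=0.01
        )

    def test_eyring_slow_exchanger(self):
        # dH = 40.0 kJ/mol, dS = +15.8 -> ~245 ns, inside the quoted 253 +/- 15
        tau = tau_eyring(298.15, dH=40.0e3, dS=15.8)
        assert tau == pytest.approx(245e-9, rel=0.01)
        assert abs(tau - 253e-9) <= 15e-9

    def test_eyring_inversion_identity(self):
        # choosing dS so that k(298) = 1/tau reproduces tau exactly
        tau = 3.3e-9
        dH = 25e3
        dS = R_GAS * math.log(H_PLANCK / (K_BOLTZMANN * 298.15 * tau)) + dH / 298.15
        assert tau_eyring(298.15, dH=dH, dS=dS) == pytest.approx(tau, rel=1e-12)
        assert tau_eyring(298.15, tau_298=tau, dH=dH) == pytest.approx(
            tau, rel=1e-12
        )

    def test_eyring_requires_a_parametrization(self):
        with pytest.raises(ValueError):
            tau_eyring(298.15)
        with pytest.raises(ValueError):
            tau_eyring(150.0, dH=9e3, dS=0.0)  # outside 200-400 K

    def test_arrhenius(self):
        assert tau_arrhenius(10.6e-12, 20.2e3, 298.15) == 10.6e-12
        assert tau_arrhenius(10.6e-12, 20.2e3, 310.0) == pytest.approx(
            7.76e-12, rel=0.005
        )
        assert tau_arrhenius(5e-12, 0.0, 350.0) == 5e-12


def _brute_force_dipolar(p, B0, T):
    """Independent closed-form evaluation (no shared code path)."""
    tau_R = p.tau_R_298 * math.exp(p.E_R / R_GAS * (1 / T - 1 / 298.15))
    k = (K_BOLTZMANN * T / H_PLANCK) * math.exp(
        p.dS_M / R_GAS - p.dH_M / (R_GAS * T)
    )
    tc = 1.0 / (1.0 / tau_R + k + 1.0 / p.tau_S)
    wH = GAMMA_1H * B0
    wS = G_ELECTRON * MU_BOHR * B0 / HBAR
    pref = (
        2.0 / 15.0 * MU0_OVER_4PI**2 * GAMMA_1H**2
        * G_ELECTRON**2 * MU_BOHR**2 * 0.75 / (p.r_MH * 1e-10) ** 6
    )
    return pref * (
        3 * tc / (1 + wH**2 * tc**2) + 7 * tc / (1 + wS**2 * tc**2)
    )


class TestInnerSphere:
    def test_dipolar_matches_brute_force_random_points(self, rng):
        for _ in range(20):
            p = InnerSphereParams(
                q=2,
                r_MH=rng.uniform(2.0, 3.5),
                A_H=rng.uniform(1e6, 3e7),
                tau_S=rng.uniform(0.1e-9, 3e-9),
                tau_R_298=rng.uniform(5e-12, 50e-12),
                E_R=rng.uniform(5e3, 30e3),
                dH_M=rng.uniform(5e3, 60e3),
                dS_M=rng.uniform(-50, 80),
            )
            B0 = rng.uniform(0.001, 3.0)
            T = rng.uniform(280, 320)
            assert dipolar_rate(p, B0, T) == pytest.approx(
                _brute_force_dipolar(p, B0, T), rel=1e-10
            )

    def test_dipolar_magnitude_and_distance_limit(self):
        p = CU_TACN.inner
        rate = dipolar_rate(p, B20, 298.15)
        assert rate == pytest.approx(6.0e3, rel=0.05)
        far = InnerSphereParams(
            q=2, r_MH=1e4, A_H=p.A_H, tau_S=p.tau_S,
            tau_R_298=p.tau_R_298, E_R=p.E_R, dH_M=p.dH_M, dS_M=p.dS_M,
        )
        assert dipolar_rate(far, B20, 298.15) < 1e-10

    def test_dipolar_monotone_above_dispersion(self):
        p = CU_TACN.inner
        fields = np.linspace(0.5, 3.0, 20)  # well above the omega_S dispersion
        rates = dipolar_rate(p, fields, 298.15)
        assert np.all(np.diff(rates) <= 0)

    def test_scalar_rate(self):
        p = CU_TACN.inner
        assert scalar_rate(p, B20, 298.15) == pytest.approx(70.0, rel=0.05)
        zero = InnerSphereParams(
            q=2, r_MH=2.56, A_H=0.0, tau_S=p.tau_S,
            tau_R_298=p.tau_R_298, E_R=p.E_R, dH_M=p.dH_M, dS_M=p.dS_M,
        )
        assert scalar_rate(zero, B20, 298.15) == 0.0
        # quadratic scaling in the coupling at fixed tau_e2
        double = InnerSphereParams(
            q=2, r_MH=2.56, A_H=2 * p.A_H, tau_S=p.tau_S,
            tau_R_298=p.tau_R_298, E_R=p.E_R, dH_M=p.dH_M, dS_M=p.dS_M,
        )
        assert scalar_rate(double, B20, 298.15) == pytest.approx(
            4 * scalar_rate(p, B20, 298.15), rel=1e-12
        )

    def test_inner_sphere_relaxivity_value_and_limits(self):
        p = CU_TACN.inner
        assert inner_sphere_relaxivity(p, B20, 298.15) == pytest.approx(
            0.22, abs=0.01
        )
        q0 = InnerSphereParams(
            q=0, r_MH=2.56, A_H=p.A_H, tau_S=p.tau_S,
            tau_R_298=p.tau_R_298, E_R=p.E_R, dH_M=p.dH_M, dS_M=p.dS_M,
        )
        assert inner_sphere_relaxivity(q0, B20, 298.15) == 0.0
        # slow-exchange quenching: huge tau_M kills the contribution
        slow = InnerSphereParams(
            q=2, r_MH=2.56, A_H=p.A_H, tau_S=p.tau_S,
            tau_R_298=p.tau_R_298, E_R=p.E_R, tau_M_298=1e4,
        )
        assert inner_sphere_relaxivity(slow, B20, 298.15) < 1e-8

    def test_eyring_consistency_enforced_on_construction(self):
        with pytest.raises(ValueError, match="disagrees"):
            InnerSphereParams(
                q=2, r_MH=2.56, A_H=8.3e6, tau_S=0.98e-9,
                tau_R_298=10.6e-12, E_R=20.2e3,
                tau_M_298=1e-9, dH_M=9.0e3, dS_M=-20.9,  # implies 75 ps
            )


class TestOuterSphere:
    def test_freed_zero_frequency_limit(self):
        from cuprelax.nmrd import _freed_J

        # tau_D/tau_S -> 0 at zero frequency: J -> 1 exactly
        assert _freed_J(0.0, 1e-10, 1e3) == pytest.approx(1.0, abs=1e-6)

    def test_magnitude_at_20MHz(self):
        val = outer_sphere_relaxivity(CU_TACN.outer, 0.98e-9, B20, 298.15)
        assert val == pytest.approx(0.097, abs=0.01)

    def test_monotone_in_closest_approach(self):
        vals = [
            outer_sphere_relaxivity(
                OuterSphereParams(a=a, D_298=2.3e-9, E_D=20e3),
                0.98e-9, B20, 298.15,
            )
            for a in (3.0, 3.6, 4.5, 6.0)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_zero_concentration_switch(self):
        assert outer_sphere_relaxivity(
            CU_TACN.outer, 0.98e-9, B20, 298.15, conc_mM=0.0
        ) == 0.0


class TestProfile:
    def test_printed_relaxivities(self):
        prof = nmrd_profile(CU_TACN.inner, CU_TACN.outer, [20.0], [298.15])
        assert prof.r1[0] == pytest.approx(0.31, rel=0.10)
        prof = nmrd_profile(CU_TREN_PH7.inner, CU_TREN_PH7.outer, [20.0], [298.15])
        assert prof.r1[0] == pytest.approx(0.23, rel=0.10)

    def test_additivity_is_exact(self):
        fields = np.geomspace(0.01, 120, 12)
        prof = nmrd_profile(CU_TACN.inner, CU_TACN.outer, fields, [298.15])
        B0 = 2 * math.pi * fields * 1e6 / GAMMA_1H
        expected = inner_sphere_relaxivity(
            CU_TACN.inner, B0, 298.15
        ) + outer_sphere_relaxivity(CU_TACN.outer, CU_TACN.inner.tau_S, B0, 298.15)
        assert prof.r1 == pytest.approx(expected, rel=1e-14)

    def test_all_relaxivities_nonnegative(self):
        fields = np.geomspace(0.01, 120, 20)
        for preset in (CU_TACN, CU_TREN_PH7):
            prof = nmrd_profile(preset.inner, preset.outer, fields, [283, 298, 310])
            assert np.all(prof.r1 >= 0)

    def test_high_field_relaxivity_drops_with_temperature(self):
        # fast-exchange regime: r1 decreases on warming at high field
        for preset in (CU_TACN, CU_TREN_PH7):
            prof = nmrd_profile(preset.inner, preset.outer, [60.0], [283, 298, 310])
            assert np.all(np.diff(prof.r1) < 0)

    def test_zero_profile(self):
        p = CU_TACN.inner
        q0 = InnerSphereParams(
            q=0, r_MH=2.56, A_H=p.A_H, tau_S=p.tau_S,
            tau_R_298=p.tau_R_298, E_R=p.E_R, dH_M=p.dH_M, dS_M=p.dS_M,
        )
        prof = nmrd_profile(q0, CU_TACN.outer, [1.0, 20.0], [298.15],
                            os_conc_mM=0.0)
        assert np.all(prof.r1 == 0.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            nmrd_profile(CU_TACN.inner, CU_TACN.outer, [], [298.15])
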