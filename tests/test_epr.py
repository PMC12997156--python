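"""CW-EPR: perturbative vs exact resonance fields, powder and fast motion."""

import numpy as np
import pytest

from cuprelax import (
    PrincipalTensor,
    SpinSystemCu,
    exact_resonance_fields,
    fast_motion_spectrum,
    fit_tau_R,
    powder_spectrum,
    resonance_fields,
    resonance_field_isotropic,
)
from cuprelax.constants import CU65_OVER_CU63
from cuprelax.epr import _redfield_widths, fibonacci_hemisphere
from cuprelax.synthetic import generate_cw_spectrum


def random_orientations(rng, n):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestResonanceFields:
    def test_isotropic_no_hyperfine_collapses(self):
        sys = SpinSystemCu(
            g=PrincipalTensor(2.0023, 2.0023, 2.0023),
            A_Cu=PrincipalTensor(0, 0, 0),
        )
        f = resonance_fields(sys, [0, 0, 1.0], 9.42e9)
        b_iso = resonance_field_isotropic(2.0023, 9.42e9) * 1e3
        assert f == pytest.approx([b_iso] * 4, abs=1e-6)

    def test_isotope_spacing_ratio(self, tacn_spin, rng):
        for v in random_orientations(rng, 5):
            f63 = np.sort(resonance_fields(tacn_spin, v, 9.42e9))
            f65 = np.sort(
                resonance_fields(tacn_spin, v, 9.42e9,
                                 isotope_scale=CU65_OVER_CU63)
            )
            span63 = f63[-1] - f63[0]
            span65 = f65[-1] - f65[0]
            assert span65 / span63 == pytest.approx(CU65_OVER_CU63, rel=5e-3)

    def test_outer_line_span_along_z(self, tacn_spin):
        # first order: span = 3|Az| in field units along the unique axis
        f = np.sort(exact_resonance_fields(tacn_spin, [0, 0, 1.0], 9.42e9))
        from cuprelax.constants import H_PLANCK, MU_BOHR

        span_expected = 3 * 482e6 * H_PLANCK / (2.288 * MU_BOHR) * 1e3  # mT
        assert f[-1] - f[0] == pytest.approx(span_expected, rel=0.01)

    @pytest.mark.parametrize("mw, tol_mT", [(9.42e9, 0.15), (33.8e9, 0.05)])
    def test_perturbation_vs_exact_oracle(self, tacn_spin, tren_spin, rng,
                                          mw, tol_mT):
        """Second-order engine within tolerance of full diagonalization."""
        for sys in (tacn_spin, tren_spin):
            errs = []
            for v in random_orientations(rng, 50):
                pt = np.sort(resonance_fields(sys, v, mw))
                ex = exact_resonance_fields(sys, v, mw)
                errs.append(np.max(np.abs(pt - ex)))
            assert max(errs) < tol_mT

    def test_non_unit_orientation_rejected(self, tacn_spin):
        with pytest.raises(ValueError, match="unit vector"):
            resonance_fields(tacn_spin, [0, 0, 2.0], 9.42e9)


class TestPowder:
    grid = np.linspace(240, 380, 1500)

    def test_integral_invariant_under_grid_doubling(self, tacn_spin):
        a = powder_spectrum(tacn_spin, 9.42e9, self.grid, "absorption",
                            n_orientations=2000)
        b = powder_spectrum(tacn_spin, 9.42e9, self.grid, "absorption",
                            n_orientations=4000)
        ia = np.trapezoid(a.ordinate, self.grid)
        ib = np.trapezoid(b.ordinate, self.grid)
        assert abs(ia - ib) / ib < 0.005

    def test_axial_pattern_and_parallel_quartet(self, tacn_spin):
        """g|| > g_perp: absorption extends to low field with an Az quartet."""
        spec = powder_spectrum(tacn_spin, 9.42e9, self.grid, "absorption",
                               n_orientations=3000)
        b_perp = resonance_field_isotropic(2.058, 9.42e9) * 1e3
        b_par = resonance_field_isotropic(2.288, 9.42e9) * 1e3
        # intensity concentrates near the perpendicular ridge
        peak_field = self.grid[np.argmax(spec.ordinate)]
        assert abs(peak_field - b_perp) < 8.0
        # parallel features occur well below, around b_par +/- hyperfine span
        low_side = spec.ordinate[self.grid < b_par + 10]
        assert low_side.max() > 0.02  # resolved low-field quartet intensity

    def test_isotropic_line_derivative_crosses_zero_at_resonance(self):
        sys = SpinSystemCu(
            g=PrincipalTensor(2.1, 2.1, 2.1), A_Cu=PrincipalTensor(0, 0, 0),
            lw_gauss_mT=1.0, lw_lorentz_mT=0.5,
        )
        grid = np.linspace(300, 340, 1200)
        spec = powder_spectrum(sys, 9.42e9, grid, "derivative")
        b0 = resonance_field_isotropic(2.1, 9.42e9) * 1e3
        # zero crossing of the derivative at the resonance field
        k = np.argmin(np.abs(grid - b0))
        window = spec.ordinate[k - 12: k + 12]
        assert window.max() * window.min() < 0  # sign change
        # symmetric line: |max| == |min| within a few percent
        assert abs(abs(spec.ordinate.max()) - abs(spec.ordinate.min())) < 0.05

    def test_permutation_of_tensor_components_is_frame_relabeling(self):
        grid = np.linspace(240, 380, 1200)
        a = powder_spectrum(
            SpinSystemCu(g=PrincipalTensor(2.058, 2.058, 2.288),
                         A_Cu=PrincipalTensor(30, 30, -482)),
            9.42e9, grid, "absorption", n_orientations=4000,
        )
        b = powder_spectrum(
            SpinSystemCu(g=PrincipalTensor(2.288, 2.058, 2.058),
                         A_Cu=PrincipalTensor(-482, 30, 30)),
            9.42e9, grid, "absorption", n_orientations=4000,
        )
        scale = np.max(np.abs(a.ordinate))
        assert np.max(np.abs(a.ordinate - b.ordinate)) / scale < 0.05

    def test_clipped_grid_warns(self, tacn_spin):
        with pytest.warns(UserWarning, match="clipped"):
            powder_spectrum(tacn_spin, 9.42e9, np.linspace(320, 340, 200),
                            "absorption", n_orientations=200)


class TestFastMotion:
    def test_widths_vanish_for_isotropic_tensors(self):
        sys = SpinSystemCu(
            g=PrincipalTensor(2.1, 2.1, 2.1),
            A_Cu=PrincipalTensor(100.0, 100.0, 100.0),
        )
        w = _redfield_widths(sys, 10e-12, 0.33, 1.0, n_dir=64)
        assert np.all(w < 1e3)  # essentially zero (numerical quadrature floor)

    def test_widths_shrink_with_faster_tumbling(self, tacn_spin):
        w_fast = _redfield_widths(tacn_spin, 1e-12, 0.33, 1.0, n_dir=64)
        w_slow = _redfield_widths(tacn_spin, 20e-12, 0.33, 1.0, n_dir=64)
        assert np.all(w_fast < w_slow)

    def test_mI_dependent_width_asymmetry(self, tacn_spin):
        # g-A cross-correlation makes the width pattern asymmetric in mI
        w = _redfield_widths(tacn_spin, 7.6e-12, 0.33, 1.0, n_dir=96)
        assert w[0] != pytest.approx(w[-1], rel=0.05)

    def test_tau_R_to_zero_reduces_to_intrinsic_lines(self, tacn_spin):
        grid = np.linspace(290, 360, 1500)
        s = fast_motion_spectrum(tacn_spin, 1e-15, 9.42e9, grid, n_dir=64)
        # all four lines collapse to the residual width: deep sharp features
        assert np.max(np.abs(s.ordinate)) == 1.0
        s2 = fast_motion_spectrum(tacn_spin, 7.6e-12, 9.42e9, grid, n_dir=64)
        # motional broadening visibly smooths the pattern
        assert np.sum(np.abs(np.diff(s.ordinate))) > np.sum(
            np.abs(np.diff(s2.ordinate))
        )

    def test_outside_narrowing_regime_warns(self, tacn_spin):
        grid = np.linspace(250, 400, 500)
        with pytest.warns(UserWarning, match="motional-narrowing"):
            fast_motion_spectrum(tacn_spin, 5e-10, 9.42e9, grid, n_dir=32)

    def test_invalid_tau_rejected(self, tacn_spin):
        with pytest.raises(ValueError):
            fast_motion_spectrum(tacn_spin, -1e-12, 9.42e9,
                                 np.linspace(300, 360, 100))


class TestFitTauR:
    def test_noiseless_self_consistency(self, tacn_spin):
        spec = generate_cw_spectrum(
            tacn_spin, regime="fast_motion", tau_R=7.6e-12, noise_frac=0.0,
            seed=0,
        )
        tau, _ = fit_tau_R(spec, tacn_spin)
        assert tau == pytest.approx(7.6e-12, rel=1e-3)

    @pytest.mark.parametrize(
        "system, tau_true", [("tacn", 7.6e-12), ("tren", 13e-12)]
    )
    def test_recovery_at_1pct_noise(self, tacn_spin, tren_spin, system,
                                    tau_true):
        sys = tacn_spin if system == "tacn" else tren_spin
        spec = generate_cw_spectrum(
            sys, regime="fast_motion", tau_R=tau_true, noise_frac=0.01, seed=7
        )
        tau, err = fit_tau_R(spec, sys)
        assert tau == pytest.approx(tau_true, rel=0.10)
        assert err > 0


def test_fibonacci_grid_covers_hemisphere_uniformly():
    pts = fibonacci_hemisphere(2000)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.all(pts[:, 2] >= 0)
    # rank-2 moment of an equal-area grid: <z^2> = 1/3
    assert np.mean(pts[:, 2] ** 2) == pytest.approx(1 / 3, abs=0.01)
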