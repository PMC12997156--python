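# Methods

This note records the models implemented in `cuprelax`, their
assumptions, the defaults and why, and the numerical choices made where
the design was genuinely open.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Relaxivity model

### Inner sphere (SBM)

Bound-water (or bound-proton) longitudinal relaxation is the sum of the
dipolar and scalar (contact) SBM rates for S = 1/2:

    1/T₁M^DD = (2/15)(μ₀/4π)² γ_H² g_e² μ_B² S(S+1) r⁻⁶
               [3τ_c/(1+ω_H²τ_c²) + 7τ_c/(1+ω_S²τ_c²)]
    1/T₁M^SC = (2/3) S(S+1) (A_H/ℏ)² τ_e2/(1+ω_S²τ_e2²)

with 1/τ_c = 1/τ_R(T) + 1/τ_M(T) + 1/τ_S and 1/τ_e2 = 1/τ_M + 1/τ_S.
Assumptions: a single, field- and temperature-independent electronic
relaxation time τ_S serves as both T1e and T2e and appears in every
correlation time (the one-τ_S model keeps the parameter count at the
level the data can support); the Curie term is omitted (negligible for
S = 1/2 at these fields); the free-electron g is used in ω_S and in the
dipolar prefactor.  Whether τ_S carries a temperature dependence across
283–310 K is unknown; the default is none, and an Arrhenius scaling hook
exists but is off.

Relaxivity per mM uses the bound mole fraction q/55 560 for q water
molecules (two equivalent protons each against 2×55.56 M bulk protons)
or q/111 120 when q counts single exchangeable protons — the hydroxo
complex case, where only the OH proton relaxes (`q_is_protons=True`).

### Outer sphere (translational diffusion)

The force-free (Freed) model:

    r₁ᴼˢ = (32π/405)(μ₀/4π)² γ_H² γ_S² ℏ² S(S+1) · N_A[C]/(a D(T))
           · [3J(ω_H) + 7J(ω_S)]
    J(ω) = Re[(1 + z/4)/(1 + z + 4z²/9 + z³/9)],
    z = √(iωτ_D + τ_D/τ_S)

**Convention note.** Two definitions of the translational correlation
time coexist in the literature, τ_D = a²/D and τ_D = 2a²/D.  This
package adopts **τ_D = 2a²/D**: with the study's fixed a = 3.6 Å and
D₂₉₈ = 2.3×10⁻⁹ m² s⁻¹ it reproduces all six reported 20 MHz
relaxivities (three complexes × two temperatures) within 2–9%, whereas
a²/D overshoots them systematically by ~11–15%.  The choice is a single
global convention, not a per-dataset adjustment.

Defaults a = 3.6 Å, D₂₉₈ = 2.3×10⁻⁹ m² s⁻¹, E_D = 20.0 kJ mol⁻¹ are the
values the benchmark analysis fixed from MD and literature.

### Temperature laws

Exchange follows Eyring transition-state theory,
k_ex = (k_B T/h)·exp(ΔS‡/R − ΔH‡/(R T)); τ_R and D follow Arrhenius laws
anchored at 298.15 K.  When both τ_M(298) and an Eyring pair are given
they must agree within 5% (validated at construction); the Eyring pair
then defines τ_M(T).

### Prototropic exchange

At strongly basic pH the observable exchange is proton transfer from a
bound hydroxide, 1/τ_M = 1/τ_M(H₂O) + [OH⁻]/τ_M(H).  The fit
parametrizes the *observed* τ_M with an Eyring pair (that is what the
data determine); the elementary proton lifetime is derived afterwards as
τ_M(H) = τ_M·[OH⁻].  [OH⁻] comes from pH via pKw = 14 at 25 °C; the
temperature dependence of Kw is deliberately ignored (it is far below
the precision at which τ_M(H) is determined).

## ¹⁷O Swift–Connick model

Reduced (per-bound-water-mole-fraction) transverse rate and shift:

    R2r = (1/τ_M)[T₂M⁻² + (T₂M τ_M)⁻¹ + Δω_M²] / [(T₂M⁻¹+τ_M⁻¹)² + Δω_M²]
    Δω_r = Δω_M / [(1 + τ_M/T₂M)² + τ_M²Δω_M²]

with a purely scalar bound-site rate
1/T₂M = (S(S+1)/3)(A_O/ℏ)²[τ_e1 + τ_e2/(1+ω_S²τ_e2²)] and the Curie-type
contact shift Δω_M = g_e μ_B S(S+1) B₀ (A_O/ℏ)/(3 k_B T).  Outer-sphere
¹⁷O contributions are neglected; a q = 0 configuration returns an
identically zero reduced dataset (the basic-pH signature).  B₀ defaults
to 11.7 T.  Fast/slow-exchange limits (R2r → 1/T₂M + τ_MΔω_M², R2r →
1/τ_M) are verified to 10⁻¹⁰ relative in the tests.

With the benchmark's slow-exchange parameters the R2r(T) curve is
exchange-limited (≈ 1/τ_M) at 270 K and bound-site-limited by 350 K; the
crossover does not produce a maximum below 350 K because the saturating
bound-site rate exceeds the decaying τ_MΔω_M² term at the crossover.

## Joint fit

Residuals are (model − data)/σ concatenated over the NMRD block and,
when present, both ¹⁷O channels.  When a dataset carries no σ, each
block defaults to 1% of its maximum observable — the relaxometer's
stated uncertainty class — which also makes the blocks commensurate; the
relative NMRD/¹⁷O weighting used in the original analysis is unstated,
and equal per-point weighting after this normalization is the documented
default.  The optimizer is trust-region-reflective least squares
(lmfit/scipy) with numerical Jacobian, finite bounds on every free
parameter, and optional seeded multi-start.  Uncertainties are the
covariance at the optimum scaled by reduced χ²; no bootstrap by default.
Fixed parameters are bit-identical before and after fitting (asserted at
run time).  Parameters are conditioned (ns, ps, kJ mol⁻¹, 10⁸/10⁶ rad
s⁻¹) so the Jacobian is well scaled.

A caveat the recovery benchmarks quantify: for the pH 12 protocol the
Eyring pair (ΔH‡, ΔS‡) is weakly identified — τ_M perturbs the low-field
relaxivity by only a few percent — so those two parameters show wide,
strongly correlated intervals, and their Wald coverage is the weakest of
the set while remaining within the benchmark's acceptance.

## CW-EPR

### Resonance fields

Second-order perturbation theory on H = μ_B B·g·S + S·A·I.  With
u = g·l/|g·l| the electron quantization axis, K = |A·u| the first-order
coupling, and n = A·u/K the nuclear axis, the microwave condition is

    ν = ν_e + K m_I + [(|A·n|² − K²) m_I²
        + (‖A‖_F² − |A·n|²)(I(I+1) − m_I²)/2] / (2ν_e),

solved as a quadratic in ν_e.  The two invariants |A·n|² and ‖A‖_F²
make the expression frame-free and valid for rhombic, Euler-rotated
tensors.  Nuclear Zeeman and quadrupole terms are omitted (they cancel
at first order for the allowed ΔmI = 0 transitions and contribute only
at order ν_n A/ν_e).  An exact 8×8 diagonalization oracle refines each
allowed transition by Newton iteration — the i-th lowest state of the
m_S = −1/2 manifold pairs with the (3−i)-th of the upper manifold —
and bounds the perturbative error: < 0.15 mT at X-band and < 0.05 mT at
Q-band for the benchmark tensors (the dominant error is third-order,
∝ A³/ν²).

### Powder averaging

Deterministic equal-area spiral on the hemisphere (default 4 000 knots;
no random sampling, for bit-reproducibility), isotope-weighted
(⁶³Cu/⁶⁵Cu at 69.17/30.83%, hyperfine scaled by the gyromagnetic ratio
quotient 1.0713), stick histogram convolved with Lorentzian then
Gaussian intrinsic lineshapes, derivative for CW and absorption for
ESE-detected spectra.  An optional refinement check warns when doubling
the grid changes the spectrum by more than 1%.  The intrinsic residual
widths used by the simulations (1.5 mT Gaussian / 0.8 mT Lorentzian
FWHM) are a package choice — the original simulations do not publish
theirs — so rigid-limit comparisons in the tests are structural
(pattern, ridge positions, quartet span), not golden-file.

### Fast motion

Line positions are the isotropic ⟨g⟩/a_iso values with the second-order
isotropic hyperfine shift.  The m_I-dependent widths are motional-
narrowing (Redfield) rates computed **numerically** rather than through
transcribed closed-form coefficients: the anisotropic Zeeman + hyperfine
Hamiltonian is sampled on a deterministic SO(3) grid (equal-area
directions × in-plane angles), and

    1/T₂(m_I) = ⟨δω²⟩ τ_R  +  ½ Σ_c [W_{+m→c} + W_{−m→c}],
    W_{a→c} = 2⟨|H₁(Ω)_{ac}|²⟩ j(ω_ac),   j(ω) = τ_R/(1+ω²τ_R²)

— the secular term plus golden-rule lifetime broadening, which is the
content of the standard fast-tumbling linewidth theory but generalizes
to rhombic, non-coaxial tensors without coefficient bookkeeping.
Isotropic tensors give zero width and τ_R → 0 collapses all lines to the
intrinsic width (both tested).  A warning is emitted when
(anisotropy)·τ_R approaches 1, outside the narrowing regime.

`fit_tau_R` is a bounded one-dimensional least squares over log₁₀τ_R
(0.1 ps–10 ns) with amplitude and baseline profiled out linearly;
uncertainty from the χ² curvature at the optimum.  Flat curvature raises
an unidentifiability error.

## Davies ENDOR

First-order frequencies only: ν(m_S) = |m_S A·u − ν_n·l|, valid in the
weak-coupling regime |A| < 2ν_n that all benchmark protons satisfy at
Q-band (ν_n ≈ 51 MHz at 1200 mT); a warning fires otherwise.  No
hyperfine enhancement factor.  Orientation selection weights each
powder orientation by a Gaussian kernel in the offset between the
working field and the orientation's resonance fields, summed over m_I
and isotopes; the kernel width maps the microwave excitation bandwidth
into field units.  The bandwidth is not published; the default 50 MHz
follows from the 16 ns inversion pulse (≈ 60 MHz nominal) and is
configurable.  Davies suppression of small couplings (the ±2 MHz matrix
region) is a single multiplicative factor η(A) = A²/(A² + Δ_h²) with a
2 MHz default hole width.  RF lineshape: Gaussian, 0.3 MHz FWHM.
Euler angles of proton tensors stay fixed at their input (DFT-derived)
values in any fitting.

Point-dipole distances invert T∥ = 2K_dd/r³ with K_dd = (μ₀/4π) g_e μ_B
g_H μ_N/h = 79.1 MHz Å³ after removing a_iso.  For real (rhombic)
tensors the estimate is approximate; the round trip on ideal axial
tensors is exact to 10⁻⁹ and the benchmark water-proton tensor lands
within 15% of the reference distance.

## Auxiliary utilities

**Autocorrelation τ_R**: single-exponential fit with amplitude pinned at
1; the fit window ends at 5 estimated τ_R or the first zero crossing,
whichever is first, because long-lag noise otherwise dominates.  An
unnormalized trace warns rather than silently rescaling; a non-decaying
trace raises.

**Evans/BMS moment**: χ_M = 3Δf/(4π f c′) (SI, cylindrical sample
parallel to B₀ — the superconducting-magnet geometry) with c′ in
mol m⁻³, then μ_eff = 797.8·√(χ_M T) μ_B, where 797.8 =
√(3k_B/(μ₀ N_A μ_B²)) pairs with χ_M in m³ mol⁻¹.  Diamagnetic
corrections are off by default; the geometry convention is recorded here
because the original report does not state it.

## Synthetic data and what passing tests show

Generators are pure functions of (truth, grid, seed): NMRD on the
study's grids (20 log-spaced fields 0.01–120 MHz × {283, 298, 310} K)
with multiplicative Gaussian noise and per-point σ; ¹⁷O on 10
temperatures 275–345 K with per-channel noise scaled to each channel's
maximum; CW spectra with additive noise scaled to the peak; MD-style
autocorrelation traces as segment-averaged exp(−t/τ_R).  Default noise
is 1% (the instrument class); recovery benchmarks use 2%.

The generators share the forward models with the fitters, so recovery
tests are inverse-crime checks by design: they validate
identifiability, optimizer correctness and uncertainty calibration
under the stated conditions, not model adequacy against real samples.
Real data add baseline drift, field-calibration error, diamagnetic
subtraction residuals and model error (second-sphere water,
field-dependent τ_S), none of which are emulated.

Benchmark problem sizes — 60 NMRD + 20 ¹⁷O points per fit, 50 recovery
replicates per preset, 50 orientations for the EPR oracle, 2 048-point
spectra, 4 000-knot powder grids — were chosen so the full validation
suite runs in a few minutes on one core while keeping every estimate's
Monte-Carlo error well below the tolerances tested.

## Known limitations

* No Curie relaxation, zero-field-splitting electron relaxation, or
  second-sphere terms (not applicable or not identifiable for S = 1/2).
* No slow-motion (stochastic-Liouville) EPR lineshapes: the fast-motion
  module warns and degrades outside ω τ_R < 1.
* No nuclear quadrupole interactions anywhere (¹⁴N superhyperfine is
  unresolved in CW-EPR and out of scope).
* ¹⁷O model has no longitudinal-relaxation or quadrupolar bound-water
  channel.
* The (ΔH‡, ΔS‡) pair of a slow, weakly coupled exchange pathway is
  close to non-identifiable from NMRD alone; treat its Wald intervals
  with care (see Joint fit).
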