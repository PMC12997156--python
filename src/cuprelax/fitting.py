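"""Joint weighted least-squares fitting of 1H NMRD and 17O NMR data.

The fit couples the SBM/Freed relaxivity model and the Swift-Connick 17O
model through their shared parameters (exchange Eyring pair, tau_R, tau_S)
and minimizes the concatenated sigma-weighted residuals with a
trust-region-reflective least-squares optimizer (lmfit/scipy).  Parameters
carry free/fixed flags and finite bounds; fixed parameters are returned
bit-identical.  One-sigma uncertainties come from the covariance at the
optimum scaled by the reduced chi-square.

Two model variants are supported:

* ``waters`` — q inner-sphere water molecules, tau_M from the Eyring pair
  (the neutral-pH protocol, NMRD + 17O fitted simultaneously);
* ``protons`` — q exchangeable protons with base-catalysed prototropic
  exchange (the hydroxo protocol, NMRD only).  The Eyring pair
  parametrizes the observed effective lifetime tau_M; the elementary
  proton residence lifetime follows from the prototropic law as
  tau_M(H) = tau_M [OH-] (see :func:`prototropic_tau_M` and
  :meth:`RelaxationParameterSet.tau_M_H_298`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import lmfit
import numpy as np

from .nmrd import (
    InnerSphereParams,
    NMRDProfile,
    OuterSphereParams,
    inner_sphere_relaxivity,
    outer_sphere_relaxivity,
)
from .o17 import B0_DEFAULT, O17Dataset, O17Params, swift_connick_reduced
from .presets import RelaxationPreset

__all__ = [
    "RelaxationParameterSet",
    "FitResult",
    "prototropic_tau_M",
    "build_residuals",
    "fit_joint",
    "oh_conc_from_pH",
]

#: (unit scale to SI, default bounds) per fittable parameter
_PARAM_TABLE = {
    "tau_S_ns": (1e-9, (0.01, 100.0)),
    "tau_R_298_ps": (1e-12, (0.5, 1000.0)),
    "E_R_kJ": (1e3, (1.0, 80.0)),
    "dH_M_kJ": (1e3, (1.0, 120.0)),
    "dS_M": (1.0, (-250.0, 250.0)),
    "A_O_1e8": (1e8, (0.05, 10.0)),
    "A_H_1e6": (1e6, (0.05, 100.0)),
    "r_MH_A": (1.0, (1.5, 4.0)),
    "q": (1.0, (0.0, 6.0)),
    "a_A": (1.0, (2.0, 6.0)),
    "D_298_1e9": (1e-9, (0.5, 10.0)),
    "E_D_kJ": (1e3, (1.0, 60.0)),
}


def oh_conc_from_pH(pH: float) -> float:
    """[OH-] in mol L^-1 from pH at 25 C (Kw = 1e-14, T dependence ignored)."""
    return 10.0 ** (pH - 14.0)


def prototropic_tau_M(
    tau_M_H2O: float | None, tau_M_H: float | None, OH_conc: float
) -> float:
    """Effective residence lifetime with base-catalysed prototropic exchange.

    1/tau_M = 1/tau_M(H2O) + [OH-]/tau_M(H).  Either contribution may be
    absent; with no active exchange pathway an explicit error is raised
    rather than silently returning an infinite lifetime.
    """
    if OH_conc < 0:
        raise ValueError("[OH-] must be non-negative")
    rate = 0.0
    if tau_M_H2O is not None:
        if tau_M_H2O <= 0:
            raise ValueError("tau_M(H2O) must be positive")
        rate += 1.0 / tau_M_H2O
    if tau_M_H is not None and OH_conc > 0:
        if tau_M_H <= 0:
            raise ValueError("tau_M(H) must be positive")
        rate += OH_conc / tau_M_H
    if rate == 0.0:
        raise ValueError(
            "no exchange pathway: both tau_M(H2O) and the prototropic term "
            "are absent (tau_M would be infinite)"
        )
    return 1.0 / rate


@dataclass
class RelaxationParameterSet:
    """Full SBM + Swift-Connick parameter vector with free/fixed control.

    Thin wrapper over :class:`lmfit.Parameters` in conditioned units (ns,
    ps, kJ mol^-1, 1e8/1e6 rad s^-1 ...).  ``variant`` selects the exchange
    model; ``OH_conc`` (mol L^-1) is used by the prototropic variant.
    """

    params: lmfit.Parameters
    variant: str = "waters"
    OH_conc: float = 0.0
    q_is_protons: bool = False
    B0_o17: float = B0_DEFAULT

    @classmethod
    def from_preset(
        cls, preset: RelaxationPreset, free: tuple[str, ...] = ()
    ) -> "RelaxationParameterSet":
        inner, outer = preset.inner, preset.outer
        values = {
            "tau_S_ns": inner.tau_S / 1e-9,
            "tau_R_298_ps": inner.tau_R_298 / 1e-12,
            "E_R_kJ": inner.E_R / 1e3,
            "dH_M_kJ": inner.dH_M / 1e3,
            "dS_M": inner.dS_M,
            "A_O_1e8": (preset.o17.A_O / 1e8) if preset.o17 else 2.0,
            "A_H_1e6": inner.A_H / 1e6,
            "r_MH_A": inner.r_MH,
            "q": inner.q,
            "a_A": outer.a,
            "D_298_1e9": outer.D_298 / 1e-9,
            "E_D_kJ": outer.E_D / 1e3,
        }
        params = lmfit.Parameters()
        for name, (_, bounds) in _PARAM_TABLE.items():
            vary = name in free
            params.add(
                name,
                value=values[name],
                vary=vary,
                min=bounds[0] if vary else -math.inf,
                max=bounds[1] if vary else math.inf,
            )
        unknown = set(free) - set(_PARAM_TABLE)
        if unknown:
            raise KeyError(f"unknown free parameters: {sorted(unknown)}")
        variant = "protons" if inner.q_is_protons else "waters"
        return cls(
            params=params,
            variant=variant,
            OH_conc=preset.OH_conc,
            q_is_protons=inner.q_is_protons,
        )

    def _si(self, p: lmfit.Parameters, name: str) -> float:
        return p[name].value * _PARAM_TABLE[name][0]

    def build_models(
        self, p: lmfit.Parameters | None = None
    ) -> tuple[InnerSphereParams, OuterSphereParams, O17Params]:
        """Materialize the physics-layer parameter objects (SI units)."""
        p = self.params if p is None else p
        dS = self._si(p, "dS_M")
        if self.variant == "protons" and self.OH_conc <= 0:
            raise ValueError("prototropic variant requires OH_conc > 0")
        inner = InnerSphereParams(
            q=self._si(p, "q"),
            r_MH=self._si(p, "r_MH_A"),
            A_H=self._si(p, "A_H_1e6"),
            tau_S=self._si(p, "tau_S_ns"),
            tau_R_298=self._si(p, "tau_R_298_ps"),
            E_R=self._si(p, "E_R_kJ"),
            dH_M=self._si(p, "dH_M_kJ"),
            dS_M=dS,
            q_is_protons=self.q_is_protons,
        )
        outer = OuterSphereParams(
            a=self._si(p, "a_A"),
            D_298=self._si(p, "D_298_1e9"),
            E_D=self._si(p, "E_D_kJ"),
        )
        o17 = O17Params(
            A_O=self._si(p, "A_O_1e8"),
            q=inner.q if not self.q_is_protons else 0.0,
            tau_S=inner.tau_S,
            dH_M=inner.dH_M,
            dS_M=inner.dS_M,
            B0=self.B0_o17,
        )
        return inner, outer, o17

    @property
    def free_names(self) -> list[str]:
        return [n for n, par in self.params.items() if par.vary]

    def tau_M_H_298(self, p: lmfit.Parameters | None = None) -> float:
        """Prototropic proton lifetime tau_M(H) at 298 K (s).

        Inverts 1/tau_M = [OH-]/tau_M(H): tau_M(H) = tau_M [OH-].
        Only meaningful for the ``protons`` variant.
        """
        from .nmrd import tau_eyring

        p = self.params if p is None else p
        if self.variant != "protons" or self.OH_conc <= 0:
            raise ValueError("tau_M(H) requires the prototropic variant")
        tau_M = tau_eyring(
            298.15, dH=self._si(p, "dH_M_kJ"), dS=self._si(p, "dS_M")
        )
        return tau_M * self.OH_conc


@dataclass
class FitResult:
    """Converged joint-fit summary.

    ``values``/``stderr`` in the conditioned fit units of
    :class:`RelaxationParameterSet`; ``residuals`` holds the per-dataset
    sigma-weighted residual vectors.
    """

    values: dict
    stderr: dict
    redchi: float
    residuals: dict
    success: bool
    nfev: int
    seed: int
    message: str = ""
    lmfit_result: object | None = dc_field(default=None, repr=False)

    @property
    def n_residuals(self) -> int:
        return sum(len(v) for v in self.residuals.values())


def _default_sigma(values: np.ndarray, frac: float = 0.01) -> np.ndarray:
    """Per-block default sigma: 1% of the observable's maximum magnitude."""
    scale = np.max(np.abs(values))
    if scale == 0:
        scale = 1.0
    return np.full_like(values, frac * scale, dtype=float)


def build_residuals(
    pset: RelaxationParameterSet,
    nmrd: NMRDProfile | None,
    o17: O17Dataset | None,
    p: lmfit.Parameters | None = None,
    split: bool = False,
):
    """Sigma-weighted (model - data) residuals over all present datasets.

    NMRD contributes one block; a 17O dataset contributes two (reduced rate
    and reduced shift).  Missing sigmas default to 1% of each block's
    maximum — the stated instrument uncertainty class — which also equalizes
    the block weighting.
    """
    if (nmrd is None or len(nmrd) == 0) and (o17 is None or len(o17) == 0):
        raise ValueError("at least one non-empty dataset is required")
    inner, outer, o17p = pset.build_models(p)
    blocks: dict[str, np.ndarray] = {}
    if nmrd is not None and len(nmrd) > 0:
        model = np.empty(len(nmrd))
        from .nmrd import _field_from_proton_MHz

        for T in np.unique(nmrd.temp_K):
            m = nmrd.temp_K == T
            B0 = _field_from_proton_MHz(nmrd.freq_MHz[m])
            model[m] = inner_sphere_relaxivity(
                inner, B0, T
            ) + outer_sphere_relaxivity(outer, inner.tau_S, B0, T)
        sigma = nmrd.sigma.copy()
        bad = ~np.isfinite(sigma) | (sigma <= 0)
        sigma[bad] = _default_sigma(nmrd.r1)[bad]
        blocks["nmrd"] = (model - nmrd.r1) / sigma
    if o17 is not None and len(o17) > 0:
        pred = np.array(
            [swift_connick_reduced(o17p, T) for T in o17.temp_K]
        )
        for j, (chan, obs, sig_col) in enumerate(
            [("o17_R2r", o17.R2r, "sigma_R2r"), ("o17_dwr", o17.dwr, "sigma_dwr")]
        ):
            sigma = o17.data[sig_col].to_numpy(dtype=float).copy()
            bad = ~np.isfinite(sigma) | (sigma <= 0)
            sigma[bad] = _default_sigma(obs)[bad]
            blocks[chan] = (pred[:, j] - obs) / sigma
    if split:
        return blocks
    return np.concatenate(list(blocks.values()))


def fit_joint(
    pset: RelaxationParameterSet,
    nmrd: NMRDProfile | None,
    o17: O17Dataset | None = None,
    seed: int = 0,
    n_multistart: int = 0,
) -> FitResult:
    """Trust-region least-squares joint fit; deterministic for a given seed.

    The seed drives only the optional multi-start (seeded perturbations of
    the free initial values within bounds, best chi-square kept).  With no
    free parameters the forward-model chi-square is reported without any
    optimizer step.  Non-convergence yields ``success=False`` with the
    best-so-far parameters, never a silent failure.
    """
    free = pset.free_names
    fixed_before = {
        n: pset.params[n].value for n in pset.params if n not in free
    }

    if not free:
        resid = build_residuals(pset, nmrd, o17, split=True)
        flat = np.concatenate(list(resid.values()))
        return FitResult(
            values={n: par.value for n, par in pset.params.items()},
            stderr={},
            redchi=float(flat @ flat) / max(len(flat), 1),
            residuals=resid,
            success=True,
            nfev=1,
            seed=seed,
        )

    n_obs = sum(
        len(d) * k
        for d, k in ((nmrd, 1), (o17, 2))
        if d is not None
    )
    if n_obs < len(free):
        raise ValueError("fewer observations than free parameters")

    def objective(p: lmfit.Parameters) -> np.ndarray:
        return build_residuals(pset, nmrd, o17, p=p)

    starts = [pset.params.copy()]
    rng = np.random.default_rng(seed)
    for _ in range(n_multistart):
        trial = pset.params.copy()
        for name in free:
            par = trial[name]
            lo, hi = par.min, par.max
            width = 0.2 * (hi - lo)
            par.value = float(
                np.clip(par.value + rng.uniform(-width, width), lo, hi)
            )
        starts.append(trial)

    best = None
    for start in starts:
        res = lmfit.minimize(objective, start, method="least_squares")
        if best is None or res.chisqr < best.chisqr:
            best = res

    for name, val in fixed_before.items():
        assert best.params[name].value == val, "fixed parameter drifted"

    resid = build_residuals(pset, nmrd, o17, p=best.params, split=True)
    stderr = {
        n: (best.params[n].stderr if best.params[n].stderr is not None else math.nan)
        for n in free
    }
    return FitResult(
        values={n: par.value for n, par in best.params.items()},
        stderr=stderr,
        redchi=float(best.redchi),
        residuals=resid,
        success=bool(best.success),
        nfev=int(best.nfev),
        seed=seed,
        message=str(getattr(best, "message", "")),
        lmfit_result=best,
    )
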