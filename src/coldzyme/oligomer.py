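"""Concentration-dependent self-association.

Exact monomer-dimer speciation by the mass-action quadratic, mapping of
the dimer fraction onto observables (hydrodynamic radius from FIDA
titrations, apparent melting temperature from DSF titrations), KD
estimation by weighted least squares in log-space, and an n-mer
generalization used for the dimer-to-tetramer assembly of the engineered
triple mutant.

The observable model is obs(M0) = obs_mono + (2[D]/[M0])*(obs_dimer -
obs_mono) with [D] from [M]^2/[D] = KD and [M] + 2[D] = [M0]; the same
functional form is reused for the apparent-Tm titration with Tm
endpoints (the thermodynamic coupling of unfolding and dissociation is
deliberately not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .fitting import FitResult, TitrationSeries, fit_curve, register_model

__all__ = [
    "AssociationParams",
    "SpeciationState",
    "dimer_concentration",
    "association_observable",
    "fit_association",
    "nmer_observable",
]


@dataclass
class AssociationParams:
    """Dimer dissociation constant plus monomer/dimer endpoint observables."""

    KD: float  # M, dimer -> 2 monomers
    obs_mono: float  # endpoint observable of the monomer (nm or K/degC)
    obs_dimer: float  # endpoint observable of the dimer

    def __post_init__(self) -> None:
        if self.KD <= 0:
            raise ValueError("KD must be positive")
        if not (np.isfinite(self.obs_mono) and np.isfinite(self.obs_dimer)):
            raise ValueError("endpoint observables must be finite")


@dataclass
class SpeciationState:
    """Monomer-dimer speciation at one total concentration."""

    M0: float  # total monomer-equivalent concentration (M)
    M: float  # free monomer (M)
    D: float  # dimer (M)


def dimer_concentration(M0, KD: float):
    """Exact dimer concentration from the mass-action quadratic.

    With conservation M + 2D = M0 and KD = M^2/D the physical root is
    D = [(4*M0 + KD) - sqrt((4*M0+KD)^2 - 16*M0^2)]/8, evaluated in the
    cancellation-free equivalent form D = 2*M0^2 / (4*M0 + KD + s) with
    s = sqrt(KD^2 + 8*KD*M0).
    """
    if KD <= 0:
        raise ValueError("KD must be positive")
    M0a = np.asarray(M0, dtype=float)
    if np.any(M0a < 0):
        raise ValueError("M0 must be non-negative")
    s = np.sqrt(KD * (KD + 8.0 * M0a))
    D = 2.0 * M0a**2 / (4.0 * M0a + KD + s)
    M = M0a - 2.0 * D
    if np.isscalar(M0) or M0a.ndim == 0:
        return SpeciationState(float(M0a), float(M), float(D))
    return [SpeciationState(float(m0), float(m), float(d)) for m0, m, d in zip(M0a, M, D)]


def dimer_fraction(M0, KD: float):
    """Fraction of monomer units in dimers, 2[D]/[M0] (vectorised)."""
    M0a = np.asarray(M0, dtype=float)
    s = np.sqrt(KD * (KD + 8.0 * M0a))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(M0a > 0, 4.0 * M0a / (4.0 * M0a + KD + s), 0.0)
    return float(frac) if frac.ndim == 0 else frac


def association_observable(M0, p: AssociationParams):
    """Observable along the monomer-dimer titration.

    obs = obs_mono + (2D/M0)*(obs_dimer - obs_mono); the M0 -> 0 limit
    is obs_mono and the M0 -> inf limit is obs_dimer.
    """
    frac = dimer_fraction(M0, p.KD)
    return p.obs_mono + frac * (p.obs_dimer - p.obs_mono)


def _association_model(M0, log10_KD, obs_mono, obs_dimer):
    return association_observable(
        M0, AssociationParams(10.0**log10_KD, obs_mono, obs_dimer)
    )


register_model("association", _association_model)


def fit_association(
    series: TitrationSeries,
    init: AssociationParams | None = None,
) -> tuple[AssociationParams, FitResult]:
    """Fit (KD, obs_mono, obs_dimer) to an observable-vs-M0 titration.

    KD is fitted as log10(KD) with bounds [-12, -2]; initialisation
    defaults to the concentration at which the observable crosses its
    half-transition.  A titration narrower than two decades in M0 is
    allowed but triggers a warning, and a flat titration leaves KD at
    its bound with the fit flagged unidentifiable via infinite stderr.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 concentrations")
    span = np.log10(series.x.max() / series.x.min()) if series.x.min() > 0 else np.inf
    if span < 2:
        warnings.warn("titration spans fewer than 2 decades; KD may be ill-determined")
    if init is None:
        y0, y1 = series.y[np.argmin(series.x)], series.y[np.argmax(series.x)]
        half = 0.5 * (y0 + y1)
        i_half = int(np.argmin(np.abs(series.y - half)))
        kd0 = float(np.clip(series.x[i_half], 1e-12, 1e-2))
        init = AssociationParams(kd0, float(y0), float(y1))
    start = {
        "log10_KD": float(np.log10(init.KD)),
        "obs_mono": init.obs_mono,
        "obs_dimer": init.obs_dimer,
    }
    bounds = {"log10_KD": (-12.0, -2.0)}
    res = fit_curve("association", series, start, bounds)
    p = res.param_estimates
    params = AssociationParams(10.0 ** p["log10_KD"], p["obs_mono"], p["obs_dimer"])
    return params, res


def nmer_fraction(M0, KD_n: float, n: int, rtol: float = 1e-12):
    """Assembled subunit fraction for n M <-> M_n with KD_n = [M]^n/[M_n].

    Solves M + n*M^n/KD_n = M0 for the free-unit concentration by
    bisection on [0, M0] (the left side is strictly increasing in M, so
    a unique root always exists); returns n*[M_n]/M0.
    """
    if n < 2:
        raise ValueError("association order must be >= 2")

    def solve_one(m0: float) -> float:
        if m0 <= 0:
            return 0.0
        lo, hi = 0.0, m0

        def g(m):
            return m + n * m**n / KD_n - m0

        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                hi = mid
            else:
                lo = mid
            if hi - lo <= rtol * max(hi, 1e-300):
                break
        m = 0.5 * (lo + hi)
        return float(n * (m**n / KD_n) / m0)

    M0a = np.asarray(M0, dtype=float)
    out = np.array([solve_one(m0) for m0 in np.atleast_1d(M0a)])
    return float(out[0]) if M0a.ndim == 0 else out


def nmer_observable(M0, KD_n: float, n: int, obs_low: float, obs_high: float):
    """Observable along an n-mer association titration.

    Maps the assembled subunit fraction linearly between the free-unit
    (obs_low) and assembled (obs_high) endpoints, generalizing the
    monomer-dimer observable model; for the engineered tetramer-forming
    variant, use n = 2 with a preformed dimer as the associating unit.
    """
    frac = nmer_fraction(M0, KD_n, n)
    return obs_low + frac * (obs_high - obs_low)
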