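"""Enzyme kinetics and activation thermodynamics for ONPG hydrolysis.

Rate laws for a cold-active GH2 beta-galactosidase assayed with the
chromogenic substrate ONPG: pH-dependent extinction of the released
o-nitrophenolate, specific activity from absorbance slopes, a biphasic
sequential two-site substrate-binding law, a two-site Mg2+ activation
ladder, Eyring analysis of kcat(T), and ionic-strength bookkeeping for
phosphate-buffered saline.

Concentrations are mol/L, temperatures K, energies cal/mol throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitting import FitResult, TitrationSeries, fit_curve, linear_fit, register_model

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "ExtinctionParams",
    "BiphasicParams",
    "MgActivationParams",
    "ActivationParams",
    "BufferComposition",
    "onp_extinction",
    "specific_activity",
    "biphasic_rate",
    "mg_activation_rate",
    "eyring_rate",
    "eyring_fit",
    "ionic_strength",
    "BUFFER_A",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants; R in cal/(mol K) to match the energy convention."""

    R: float = 1.987204258640832  # cal/(mol K)
    kB: float = 1.380649e-23  # J/K
    h: float = 6.62607015e-34  # J s
    NA: float = 6.02214076e23  # 1/mol


CONSTANTS = PhysicalConstants()


@dataclass
class ExtinctionParams:
    """Extinction of the deprotonated chromophore and its pKa."""

    eps_deprotonated: float = 4600.0  # M^-1 cm^-1
    pKa: float = 7.2

    def __post_init__(self) -> None:
        if self.eps_deprotonated <= 0:
            raise ValueError("eps_deprotonated must be positive")
        if not 0 < self.pKa < 14:
            raise ValueError("pKa must be in (0, 14)")


@dataclass
class BiphasicParams:
    """Two sequential substrate-binding sites E + 2S <-> E:S <-> E:S2."""

    kcat1: float  # turnover of E:S (rate units, e.g. U/mg)
    kcat2: float  # turnover of E:S2
    K1: float  # dissociation constant of the first binding step (M)
    K2: float  # dissociation constant of the second binding step (M)

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1 and K2 must be positive")
        if self.kcat1 < 0 or self.kcat2 < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass
class MgActivationParams:
    """Three-state Mg2+ ladder: zero, one, two ions bound."""

    kcat_a: float  # rate with no Mg2+
    kcat_b: float  # rate with one Mg2+
    kcat_c: float  # rate with two Mg2+
    KA: float  # dissociation constant of the first ion (M)
    KB: float  # dissociation constant of the second ion (M)

    def __post_init__(self) -> None:
        if self.KA <= 0 or self.KB <= 0:
            raise ValueError("KA and KB must be positive")
        if min(self.kcat_a, self.kcat_b, self.kcat_c) < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass
class ActivationParams:
    """Transition-state activation parameters of the Eyring relation."""

    dH_act: float  # cal/mol
    dS_act: float  # cal/(mol K)
    kappa: float = 1.0  # transmission coefficient

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def onp_extinction(pH, params: ExtinctionParams | None = None):
    """Extinction coefficient of ONP at a given pH.

    eps(pH) = eps_ONP- * 10^(pH-pKa) / (1 + 10^(pH-pKa)); only the
    deprotonated phenolate absorbs at 420 nm, so the coefficient follows
    its Henderson-Hasselbalch ionisation fraction.
    """
    p = params or ExtinctionParams()
    frac = 1.0 / (1.0 + 10.0 ** (p.pKa - np.asarray(pH, dtype=float)))
    return p.eps_deprotonated * frac


def specific_activity(abs_slope, extinction, path_cm, enzyme_conc):
    """Specific activity in U/mg from an absorbance slope.

    Beer-Lambert: ``abs_slope/(extinction*path_cm)`` is the product
    formation rate in M/min; converted to umol/min per mg of enzyme in
    the cuvette (``enzyme_conc`` in mg/mL).
    """
    if extinction <= 0 or path_cm <= 0:
        raise ValueError("extinction and path length must be positive")
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    molar_per_min = np.asarray(abs_slope, dtype=float) / (extinction * path_cm)
    umol_per_min_per_ml = molar_per_min * 1e6 / 1e3  # M/min -> umol/(min mL)
    return umol_per_min_per_ml / enzyme_conc


def biphasic_rate(S, params: BiphasicParams):
    """Observed turnover under the sequential two-site binding scheme.

    kobs = (kcat1 + kcat2*S/K2) / (1 + K1/S + S/K2); the S -> 0 limit is 0
    and the S -> inf limit is kcat2.
    """
    S = np.asarray(S, dtype=float)
    with np.errstate(divide="ignore"):
        num = params.kcat1 + params.kcat2 * S / params.K2
        den = 1.0 + params.K1 / S + S / params.K2
        out = np.where(S > 0, num / den, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def mg_activation_rate(mg, params: MgActivationParams):
    """Observed rate as a function of free Mg2+ under the two-site ladder.

    kobs = (kcat_a*KA/mg + kcat_b + kcat_c*mg/KB) / (KA/mg + 1 + mg/KB);
    limits kcat_a (mg -> 0) and kcat_c (mg -> inf).
    """
    mg = np.asarray(mg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = params.kcat_a * params.KA / mg + params.kcat_b + params.kcat_c * mg / params.KB
        den = params.KA / mg + 1.0 + mg / params.KB
        out = np.where(mg > 0, num / den, params.kcat_a)
    if out.ndim == 0:
        return float(out)
    return out


def eyring_rate(T, params: ActivationParams, constants: PhysicalConstants = CONSTANTS):
    """Eyring rate k(T) = kappa*(kB*T/h)*exp(-dH/RT + dS/R)."""
    T = np.asarray(T, dtype=float)
    R = constants.R
    return (
        params.kappa
        * constants.kB
        * T
        / constants.h
        * np.exp(-params.dH_act / (R * T) + params.dS_act / R)
    )


def _eyring_segment(temps, rates, constants) -> tuple[ActivationParams, FitResult]:
    if temps.size < 3:
        raise ValueError("need at least 3 points per Eyring segment")
    x = 1.0 / temps
    y = np.log(rates / temps)
    res = linear_fit(x, y)
    R = constants.R
    dH = -res["slope"] * R
    dS = (res["intercept"] - np.log(constants.kB / constants.h)) * R
    dH_se = res.stderr("slope") * R
    dS_se = res.stderr("intercept") * R
    params = ActivationParams(dH_act=dH, dS_act=dS, kappa=1.0)
    fit = FitResult(
        param_estimates={"dH_act": dH, "dS_act": dS},
        param_uncertainties={"dH_act": dH_se, "dS_act": dS_se},
        residuals=res.residuals,
        reduced_chi2=res.reduced_chi2,
        converged=True,
        n_obs=int(temps.size),
        n_params=2,
    )
    return params, fit


def eyring_fit(
    temps,
    rates,
    breakpoint: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
):
    """Eyring regression of ln(k/T) on 1/T with kappa = 1.

    slope = -dH_act/R and intercept = ln(kB/h) + dS_act/R.  With
    ``breakpoint`` (K) the data are split into a cold and a warm segment
    fitted independently — useful when the plot shows a kink (here around
    300 K) — and a list of two (params, fit) pairs is returned.
    """
    temps = np.asarray(temps, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive (K)")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if breakpoint is None:
        return _eyring_segment(temps, rates, constants)
    cold = temps <= breakpoint
    warm = ~cold
    return [
        _eyring_segment(temps[m], rates[m], constants) for m in (cold, warm)
    ]


# --- ionic strength -------------------------------------------------------

#: known salts: formula -> list of (species, charge, stoichiometry).
#: ``"phosphate"`` marks the pH-speciated anion pool.
_SALTS = {
    "NaCl": [("Na+", 1, 1), ("Cl-", -1, 1)],
    "KCl": [("K+", 1, 1), ("Cl-", -1, 1)],
    "MgCl2": [("Mg2+", 2, 1), ("Cl-", -1, 2)],
    "CaCl2": [("Ca2+", 2, 1), ("Cl-", -1, 2)],
    "Na2HPO4": [("Na+", 1, 2), ("phosphate", 0, 1)],
    "KH2PO4": [("K+", 1, 1), ("phosphate", 0, 1)],
    "NaH2PO4": [("Na+", 1, 1), ("phosphate", 0, 1)],
    "K2HPO4": [("K+", 1, 2), ("phosphate", 0, 1)],
}


@dataclass
class BufferComposition:
    """Formal salt composition with pH for phosphate speciation.

    ``salts`` maps formula to formal concentration in mM.  Only the
    second phosphate ionisation (H2PO4- / HPO4^2-) is speciated, via
    Henderson-Hasselbalch at the stated pH; other protonation states are
    negligible near neutrality.  Cations are counted at formal
    concentrations.
    """

    salts: dict[str, float] = field(default_factory=dict)
    pH: float = 7.0
    phosphate_pKa2: float = 7.2

    def __post_init__(self) -> None:
        for name, conc in self.salts.items():
            if name not in _SALTS:
                raise ValueError(f"unknown salt {name!r}; known: {sorted(_SALTS)}")
            if conc < 0:
                raise ValueError("concentrations must be non-negative")


#: PBS + 0.1 mM MgCl2, the assay buffer ("buffer A"): 137 mM NaCl,
#: 2.7 mM KCl, 8 mM Na2HPO4, 2 mM KH2PO4, 0.1 mM MgCl2, pH 7.0.
BUFFER_A = BufferComposition(
    salts={"NaCl": 137.0, "KCl": 2.7, "Na2HPO4": 8.0, "KH2PO4": 2.0, "MgCl2": 0.1},
    pH=7.0,
)


def ionic_strength(buffer: BufferComposition) -> float:
    """Ionic strength I = 1/2 * sum(c_i z_i^2) in mM after speciation.

    The total phosphate pool is split between H2PO4- (z=-1) and HPO4^2-
    (z=-2) at the buffer pH using pKa2.
    """
    total = 0.0
    phosphate_mM = 0.0
    for name, conc in buffer.salts.items():
        for species, charge, stoich in _SALTS[name]:
            if species == "phosphate":
                phosphate_mM += conc * stoich
            else:
                total += conc * stoich * charge**2
    if phosphate_mM > 0:
        f_hpo4 = 1.0 / (1.0 + 10.0 ** (buffer.phosphate_pKa2 - buffer.pH))
        hpo4 = phosphate_mM * f_hpo4
        h2po4 = phosphate_mM * (1.0 - f_hpo4)
        total += hpo4 * 4 + h2po4 * 1
    return 0.5 * total


# --- model registry hooks -------------------------------------------------

def _biphasic_model(S, kcat1, kcat2, K1, K2):
    return biphasic_rate(S, BiphasicParams(kcat1, kcat2, max(K1, 1e-300), max(K2, 1e-300)))


def _mg_model(mg, kcat_a, kcat_b, kcat_c, KA, KB):
    return mg_activation_rate(
        mg, MgActivationParams(kcat_a, kcat_b, kcat_c, max(KA, 1e-300), max(KB, 1e-300))
    )


register_model("biphasic", _biphasic_model)
register_model("mg", _mg_model)


def fit_biphasic(
    data: TitrationSeries,
    init: BiphasicParams,
    n_starts: int = 1,
    seed: int = 0,
) -> tuple[BiphasicParams, FitResult]:
    """Fit the sequential two-site rate law; optional seeded multi-start.

    The loss surface can be multimodal when the two binding phases are
    poorly separated, hence the multi-start option (log-normal jitter on
    the initial K's).
    """
    bounds = {
        "kcat1": (0, np.inf),
        "kcat2": (0, np.inf),
        "K1": (1e-12, np.inf),
        "K2": (1e-12, np.inf),
    }
    base = {"kcat1": init.kcat1, "kcat2": init.kcat2, "K1": init.K1, "K2": init.K2}
    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(1, n_starts)):
        start = dict(base)
        if i > 0:
            start["K1"] = base["K1"] * 10 ** rng.uniform(-1, 1)
            start["K2"] = base["K2"] * 10 ** rng.uniform(-1, 1)
        res = fit_curve("biphasic", data, start, bounds)
        ssr = float(np.nansum(res.residuals**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    res = best[1]
    p = res.param_estimates
    return BiphasicParams(p["kcat1"], p["kcat2"], p["K1"], p["K2"]), res


def fit_mg_activation(
    data: TitrationSeries, init: MgActivationParams
) -> tuple[MgActivationParams, FitResult]:
    """Fit the two-site Mg2+ activation ladder."""
    bounds = {
        "kcat_a": (0, np.inf),
        "kcat_b": (0, np.inf),
        "kcat_c": (0, np.inf),
        "KA": (1e-12, np.inf),
        "KB": (1e-12, np.inf),
    }
    start = {
        "kcat_a": init.kcat_a,
        "kcat_b": init.kcat_b,
        "kcat_c": init.kcat_c,
        "KA": init.KA,
        "KB": init.KB,
    }
    res = fit_curve("mg", data, start, bounds)
    p = res.param_estimates
    return MgActivationParams(p["kcat_a"], p["kcat_b"], p["kcat_c"], p["KA"], p["KB"]), res
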