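"""Chemical and thermal stability fits.

Isothermal urea denaturation (two- and three-state with linear baselines,
base-10 exponent convention), van 't Hoff thermal transitions (single and
sequential double), DSF inflection-point extraction from 330/350 nm ratio
scans, generic sigmoid midpoint fits, cosolute (trehalose) stabilization
slopes, and refolding-recovery bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .fitting import FitResult, TitrationSeries, fit_curve, linear_fit, register_model
from .kinetics import CONSTANTS

__all__ = [
    "TwoStateParams",
    "ThreeStateParams",
    "ThermalTransition",
    "SigmoidParams",
    "two_state_signal",
    "three_state_signal",
    "thermal_signal",
    "dsf_inflection",
    "fit_two_state",
    "fit_three_state",
    "fit_thermal",
    "sigmoid_midpoint_fit",
    "stabilization_slope",
    "recovery_fraction",
    "m_value_to_natural",
]

#: RT at 25 C in cal/mol, the default thermal energy of the isothermal fits.
RT_25C = CONSTANTS.R * 298.15


@dataclass
class TwoStateParams:
    """Two-state denaturation: linear baselines + one transition.

    The equilibrium constant follows the printed base-10 convention
    K = 10^(m_DN*(u - u50)/RT), so ``m_DN`` carries log10 units
    (cal/(mol*M) on a log10 scale).  Use :func:`m_value_to_natural`
    for the conventional natural-log m-value.
    """

    alpha_N: float
    beta_N: float
    alpha_D: float
    beta_D: float
    m_DN: float
    u50: float
    RT: float = RT_25C

    def __post_init__(self) -> None:
        if self.u50 < 0:
            raise ValueError("u50 must be non-negative")
        if self.RT <= 0:
            raise ValueError("RT must be positive")


@dataclass
class ThreeStateParams:
    """Three-state denaturation N <-> I <-> D with an intermediate baseline."""

    alpha_N: float
    beta_N: float
    alpha_I: float
    beta_I: float
    alpha_D: float
    beta_D: float
    m_IN: float
    m_DI: float
    u50_I: float
    u50_D: float
    RT: float = RT_25C

    def __post_init__(self) -> None:
        if self.u50_I > self.u50_D:
            raise ValueError("u50_I must not exceed u50_D")
        if self.RT <= 0:
            raise ValueError("RT must be positive")


@dataclass
class ThermalTransition:
    """One van 't Hoff transition: midpoint and effective enthalpy."""

    tm: float  # K
    dH_vH: float  # cal/mol

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError("tm must be positive (K)")
        if self.dH_vH <= 0:
            raise ValueError("dH_vH must be positive for a cooperative transition")


@dataclass
class SigmoidParams:
    """Hill-type sigmoid between two plateaus with midpoint A50."""

    S_min: float
    S_max: float
    A50: float
    S_f: float

    def __post_init__(self) -> None:
        if self.S_f == 0:
            raise ValueError("slope factor must be nonzero")


def two_state_signal(u, p: TwoStateParams):
    """Signal of a two-state unfolding curve with linear baselines.

    Signal = [aN + bN*u + (aD + bD*u)*K] / (1 + K),
    K = 10^(m_DN*(u - u50)/RT).
    """
    u = np.asarray(u, dtype=float)
    logK = p.m_DN * (u - p.u50) / p.RT
    K = 10.0**np.clip(logK, -300, 300)
    sig = (p.alpha_N + p.beta_N * u + (p.alpha_D + p.beta_D * u) * K) / (1.0 + K)
    return float(sig) if sig.ndim == 0 else sig


def three_state_signal(u, p: ThreeStateParams):
    """Population-weighted three-state signal.

    Weights 1 : K1 : K1*K2 with K1 = 10^(m_IN*(u-u50_I)/RT) and
    K2 = 10^(m_DI*(u-u50_D)/RT); reduces to the two-state form when the
    second transition is pushed to infinite denaturant.
    """
    u = np.asarray(u, dtype=float)
    logK1 = np.clip(p.m_IN * (u - p.u50_I) / p.RT, -300, 300)
    logK2 = np.clip(p.m_DI * (u - p.u50_D) / p.RT, -300, 300)
    K1 = 10.0**logK1
    K1K2 = 10.0**np.clip(logK1 + logK2, -300, 300)
    num = (
        p.alpha_N
        + p.beta_N * u
        + (p.alpha_I + p.beta_I * u) * K1
        + (p.alpha_D + p.beta_D * u) * K1K2
    )
    den = 1.0 + K1 + K1K2
    sig = num / den
    return float(sig) if sig.ndim == 0 else sig


def two_state_fractions(u, p: TwoStateParams):
    """(folded, unfolded) population fractions at denaturant u."""
    u = np.asarray(u, dtype=float)
    K = 10.0**np.clip(p.m_DN * (u - p.u50) / p.RT, -300, 300)
    fU = K / (1.0 + K)
    return 1.0 - fU, fU


def thermal_signal(
    T,
    transitions: list[ThermalTransition] | ThermalTransition,
    baselines: list[tuple[float, float]],
    constants=CONSTANTS,
):
    """Thermal unfolding signal with linear baselines.

    Each transition contributes a van 't Hoff equilibrium constant
    K_i(T) = exp[-(dH_i/R)*(1/T - 1/tm_i)].  For one transition the
    signal interpolates between the native and denatured baselines; for
    two the model is sequential (N -> I -> D, populations 1 : K1 : K1*K2)
    and ``baselines`` must list (intercept, slope) for N, I, D.
    Baseline intercepts are referenced to T = 0 K.
    """
    if isinstance(transitions, ThermalTransition):
        transitions = [transitions]
    T = np.asarray(T, dtype=float)
    n = len(transitions)
    if len(baselines) != n + 1:
        raise ValueError("need one baseline per state (n_transitions + 1)")
    R = constants.R
    logKs = [
        np.clip(-(tr.dH_vH / R) * (1.0 / T - 1.0 / tr.tm), -300, 300)
        for tr in transitions
    ]
    # populations 1, K1, K1*K2, ...
    weights = [np.zeros_like(T)]
    for i in range(n):
        weights.append(weights[-1] + logKs[i])
    ws = [np.exp(w) for w in weights]
    den = sum(ws)
    num = sum(
        (a + b * T) * w for (a, b), w in zip(baselines, ws)
    )
    sig = num / den
    return float(sig) if sig.ndim == 0 else sig


def dsf_inflection(
    curve: TitrationSeries,
    smooth_window: int = 11,
    polyorder: int = 3,
    prominence_frac: float = 0.05,
):
    """Melting midpoint from a DSF ratio-vs-temperature scan.

    The inflection point is the extremum of the Savitzky-Golay smoothed
    first derivative, refined by parabolic interpolation around the
    discrete peak.  A flat scan (peak prominence below
    ``prominence_frac`` of the derivative range) yields ``None``.
    Temperatures are returned in the unit of the input grid.
    """
    T = curve.x
    y = curve.y
    if T.size < 11:
        raise ValueError("need at least 11 points")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    window = min(smooth_window, T.size if T.size % 2 else T.size - 1)
    if window <= polyorder:
        window = polyorder + 2 if (polyorder % 2) else polyorder + 3
    dT = float(np.mean(np.diff(T)))
    dy = savgol_filter(y, window, polyorder, deriv=1, delta=dT)
    # orient so the transition appears as a maximum
    mag = np.abs(dy)
    i = int(np.argmax(mag))
    span = float(mag.max() - mag.min())
    rng = float(np.ptp(dy))
    if rng == 0 or span < prominence_frac * rng or _is_flat(dy, prominence_frac):
        return None
    s = np.sign(dy[i]) or 1.0
    d = s * dy
    if 0 < i < T.size - 1:
        y0, y1, y2 = d[i - 1], d[i], d[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -1, 1))
        return float(T[i] + delta * dT)
    return float(T[i])


def _is_flat(dy: np.ndarray, prominence_frac: float) -> bool:
    """True when the derivative has no distinct peak over its baseline."""
    peak = np.max(np.abs(dy))
    baseline = np.median(np.abs(dy))
    return peak < baseline * (1.0 + prominence_frac) or peak == 0.0


# --- fits -----------------------------------------------------------------

def _two_state_model(u, alpha_N, beta_N, alpha_D, beta_D, m_DN, u50, RT):
    return two_state_signal(
        u, TwoStateParams(alpha_N, beta_N, alpha_D, beta_D, m_DN, max(u50, 0.0), RT)
    )


def _three_state_model(
    u, alpha_N, beta_N, alpha_I, beta_I, alpha_D, beta_D, m_IN, m_DI, u50_I, u50_D, RT
):
    u50_D = max(u50_D, u50_I)
    return three_state_signal(
        u,
        ThreeStateParams(
            alpha_N, beta_N, alpha_I, beta_I, alpha_D, beta_D, m_IN, m_DI, u50_I, u50_D, RT
        ),
    )


register_model("two_state", _two_state_model)
register_model("three_state", _three_state_model)


def fit_two_state(
    data: TitrationSeries, init: TwoStateParams, fix_baseline_slopes: bool = False
) -> tuple[TwoStateParams, FitResult]:
    """Fit the two-state denaturation curve; RT is held fixed."""
    start = {
        "alpha_N": init.alpha_N,
        "beta_N": init.beta_N,
        "alpha_D": init.alpha_D,
        "beta_D": init.beta_D,
        "m_DN": init.m_DN,
        "u50": init.u50,
    }
    fixed = {"RT": init.RT}
    if fix_baseline_slopes:
        fixed["beta_N"] = start.pop("beta_N")
        fixed["beta_D"] = start.pop("beta_D")
    bounds = {"u50": (0.0, np.inf)}
    res = fit_curve("two_state", data, start, bounds, fixed=fixed)
    p = {**fixed, **res.param_estimates}
    return (
        TwoStateParams(
            p["alpha_N"], p["beta_N"], p["alpha_D"], p["beta_D"], p["m_DN"], p["u50"], p["RT"]
        ),
        res,
    )


def fit_three_state(
    data: TitrationSeries, init: ThreeStateParams
) -> tuple[ThreeStateParams, FitResult]:
    """Fit the three-state curve; box constraint u50_I <= u50_D prevents
    label switching between the two transitions."""
    start = {
        "alpha_N": init.alpha_N,
        "beta_N": init.beta_N,
        "alpha_I": init.alpha_I,
        "beta_I": init.beta_I,
        "alpha_D": init.alpha_D,
        "beta_D": init.beta_D,
        "m_IN": init.m_IN,
        "m_DI": init.m_DI,
        "u50_I": init.u50_I,
        "u50_D": init.u50_D,
    }
    mid = 0.5 * (init.u50_I + init.u50_D)
    bounds = {"u50_I": (0.0, mid), "u50_D": (mid, np.inf)}
    res = fit_curve("three_state", data, start, bounds, fixed={"RT": init.RT})
    p = {**res.param_estimates, "RT": init.RT}
    return (
        ThreeStateParams(
            p["alpha_N"], p["beta_N"], p["alpha_I"], p["beta_I"], p["alpha_D"],
            p["beta_D"], p["m_IN"], p["m_DI"], p["u50_I"], p["u50_D"], p["RT"],
        ),
        res,
    )


def _thermal1_model(T, tm, dH, aN, bN, aD, bD):
    return thermal_signal(T, ThermalTransition(max(tm, 1e-6), max(dH, 1e-6)), [(aN, bN), (aD, bD)])


def _thermal2_model(T, tm1, dH1, tm2, dH2, aN, bN, aI, bI, aD, bD):
    return thermal_signal(
        T,
        [ThermalTransition(max(tm1, 1e-6), max(dH1, 1e-6)),
         ThermalTransition(max(tm2, 1e-6), max(dH2, 1e-6))],
        [(aN, bN), (aI, bI), (aD, bD)],
    )


register_model("thermal1", _thermal1_model)
register_model("thermal2", _thermal2_model)


def fit_thermal(
    data: TitrationSeries,
    init_transitions: list[ThermalTransition],
    init_baselines: list[tuple[float, float]],
) -> tuple[list[ThermalTransition], list[tuple[float, float]], FitResult]:
    """Fit one or two sequential van 't Hoff transitions with linear baselines."""
    n = len(init_transitions)
    if n == 1:
        (aN, bN), (aD, bD) = init_baselines
        start = {
            "tm": init_transitions[0].tm, "dH": init_transitions[0].dH_vH,
            "aN": aN, "bN": bN, "aD": aD, "bD": bD,
        }
        bounds = {"tm": (1.0, np.inf), "dH": (1.0, np.inf)}
        res = fit_curve("thermal1", data, start, bounds)
        p = res.param_estimates
        return (
            [ThermalTransition(p["tm"], p["dH"])],
            [(p["aN"], p["bN"]), (p["aD"], p["bD"])],
            res,
        )
    if n == 2:
        (aN, bN), (aI, bI), (aD, bD) = init_baselines
        t1, t2 = init_transitions
        mid = 0.5 * (t1.tm + t2.tm)
        start = {
            "tm1": t1.tm, "dH1": t1.dH_vH, "tm2": t2.tm, "dH2": t2.dH_vH,
            "aN": aN, "bN": bN, "aI": aI, "bI": bI, "aD": aD, "bD": bD,
        }
        bounds = {
            "tm1": (1.0, mid), "tm2": (mid, np.inf),
            "dH1": (1.0, np.inf), "dH2": (1.0, np.inf),
        }
        res = fit_curve("thermal2", data, start, bounds)
        p = res.param_estimates
        return (
            [ThermalTransition(p["tm1"], p["dH1"]), ThermalTransition(p["tm2"], p["dH2"])],
            [(p["aN"], p["bN"]), (p["aI"], p["bI"]), (p["aD"], p["bD"])],
            res,
        )
    raise ValueError("supported: 1 or 2 transitions")


def _sigmoid_model(x, S_min, S_max, A50, S_f):
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x > 0, A50 / x, np.inf)
        out = S_min + (S_max - S_min) / (1.0 + ratio**S_f)
    return np.where(x > 0, out, S_min if S_f > 0 else S_max)


register_model("sigmoid", _sigmoid_model)


def sigmoid_signal(x, p: SigmoidParams):
    """S = S_min + (S_max - S_min) / (1 + (A50/x)^S_f)."""
    return _sigmoid_model(np.asarray(x, dtype=float), p.S_min, p.S_max, p.A50, p.S_f)


def sigmoid_midpoint_fit(
    series: TitrationSeries, direction: str = "increasing"
) -> tuple[SigmoidParams, FitResult]:
    """Fit the Hill-type sigmoid; A50 is the reported midpoint.

    Used e.g. for the aggregation-midpoint analysis of scattering counts
    versus cosolute concentration.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 points")
    lo, hi = float(series.y.min()), float(series.y.max())
    a50_guess = float(np.median(series.x[series.x > 0])) if np.any(series.x > 0) else 1.0
    sf = 2.0 if direction == "increasing" else -2.0
    start = {"S_min": lo, "S_max": hi, "A50": a50_guess, "S_f": sf}
    bounds = {"A50": (1e-12, np.inf)}
    res = fit_curve("sigmoid", series, start, bounds)
    p = res.param_estimates
    return SigmoidParams(p["S_min"], p["S_max"], p["A50"], p["S_f"]), res


def stabilization_slope(tm_series: TitrationSeries) -> tuple[float, FitResult]:
    """Cosolute stabilization slope (deg C per M) by ordinary least squares."""
    if len(tm_series) < 3:
        raise ValueError("need at least 3 points")
    res = linear_fit(tm_series.x, tm_series.y)
    return res["slope"], res


def recovery_fraction(
    refolded_signal: float,
    native_signal: float,
    sigma_refolded: float | None = None,
    sigma_native: float | None = None,
):
    """Refolding recovery 100*refolded/native (%), with propagated error."""
    if native_signal == 0:
        raise ValueError("native signal must be nonzero")
    frac = 100.0 * refolded_signal / native_signal
    if sigma_refolded is None and sigma_native is None:
        return frac
    sr = sigma_refolded or 0.0
    sn = sigma_native or 0.0
    if refolded_signal:
        err = abs(frac) * np.sqrt((sr / refolded_signal) ** 2 + (sn / native_signal) ** 2)
    else:
        err = 100.0 * sr / abs(native_signal)
    return frac, float(err)


def m_value_to_natural(m_log10: float) -> float:
    """Convert the printed log10-convention m-value to the conventional
    natural-log free-energy slope in cal/(mol*M): m_nat = ln(10)*m_log10."""
    return float(np.log(10.0) * m_log10)
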