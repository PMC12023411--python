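"""Small-angle X-ray scattering: forward model, model-free analysis, and
rigid-body Monte Carlo refinement.

The forward model is a residue-bead Debye sum with a simple hydration
term: each structure is coarse-grained to one bead per residue and
I(q) = scale * sum_ij w_i w_j sinc(q r_ij) + background, where
solvent-exposed beads (neighbour count below a burial threshold) carry a
hydration-weight increment scaled by rho_hydration.  Model-free tools
cover Guinier analysis, regularized indirect Fourier transformation to
p(r), q-window summaries, and molar mass from the forward intensity
M = I(0)*NA/(c*drho_m^2).  The refinement splits the structure into
three rigid parts connected by loop anchors and walks them with a
Metropolis Monte Carlo under a profile chi^2 objective with soft
distance restraints and excluded-volume (clash) penalties.

q is the scattering-vector modulus 4*pi*sin(theta)/lambda in 1/A;
coordinates are in A, intensities in 1/cm on absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from scipy.spatial.distance import pdist, squareform

from .fitting import FitResult, linear_fit
from .kinetics import CONSTANTS

__all__ = [
    "SAXSCurve",
    "BeadStructure",
    "ScatterFitParams",
    "MassInputs",
    "MCConfig",
    "PrResult",
    "debye_intensity",
    "guinier_fit",
    "pr_invert",
    "mass_from_i0",
    "q_window_summary",
    "chi2_fit",
    "rigid_body_mc",
    "superpose_rmsd",
]


@dataclass
class SAXSCurve:
    """Scattering curve I(q) with per-point uncertainties."""

    q: np.ndarray  # 1/A, strictly increasing
    I: np.ndarray  # 1/cm
    sigma: np.ndarray | None = None
    wavelength: float = 1.34  # A (Ga metal-jet source)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if np.any(np.diff(self.q) <= 0) or np.any(self.q <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class BeadStructure:
    """Coarse-grained bead model: one bead per residue (CA or centroid)."""

    coords: np.ndarray  # (N, 3) in A
    weights: np.ndarray | None = None  # effective scattering lengths
    parts: np.ndarray | None = None  # integer part label per bead
    residue_ids: np.ndarray | None = None
    chain_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if n == 0:
            raise ValueError("structure must contain at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
        if self.parts is not None:
            self.parts = np.asarray(self.parts)

    def __len__(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BeadStructure":
        return replace(self, coords=self.coords @ rotation.T + translation)


@dataclass
class ScatterFitParams:
    """Fitted scalars of a model-to-data comparison."""

    scale: float  # concentration-proportional factor
    rho_hydration: float = 0.65  # hydration-layer contribution, in [0.2, 1.3]
    background: float = 0.0  # constant, 1/cm

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0.2 <= self.rho_hydration <= 1.3:
            raise ValueError("rho_hydration must lie in [0.2, 1.3]")


@dataclass
class MassInputs:
    """Inputs of the forward-intensity mass estimate."""

    I0: float  # 1/cm
    c: float  # g/cm^3 (1 mg/mL = 1e-3 g/cm^3)
    drho_m: float = 2.0e10  # cm/g, typical protein contrast per mass
    NA: float = CONSTANTS.NA

    def __post_init__(self) -> None:
        if min(self.I0, self.drho_m, self.NA) <= 0:
            raise ValueError("all inputs must be positive")
        if self.c <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class MCConfig:
    """Knobs of the rigid-body Monte Carlo refinement."""

    n_steps: int = 100
    n_runs: int = 10
    max_rotation_deg: float = 5.0
    max_translation: float = 2.0  # A
    anchors: list[tuple[int, int]] = field(default_factory=list)  # bead index pairs
    rest_length: float = 8.0  # A, loop slack before the spring engages
    spring_weight: float = 1.0
    clash_cutoff: float = 3.5  # A
    clash_weight: float = 0.1
    temperature: float = 0.5  # Metropolis acceptance scale, objective units
    seed: int = 0
    greedy: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_runs < 1:
            raise ValueError("n_steps and n_runs must be >= 1")
        if self.spring_weight < 0 or self.clash_weight < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class PrResult:
    """Pair-distance distribution and its integral summaries."""

    r: np.ndarray
    pr: np.ndarray
    Dmax: float
    Rg: float
    I0: float
    flagged: bool = False  # systematic residual trend (Dmax likely too small)


# --- forward model --------------------------------------------------------

_BURIAL_NEIGHBORS = 11  # beads within 7.3 A; fewer marks the bead exposed
_BURIAL_RADIUS = 7.3  # A
_HYDRATION_GAIN = 0.1  # weight increment per unit rho_hydration on exposed beads


def effective_weights(structure: BeadStructure, rho_hydration: float) -> np.ndarray:
    """Bead weights with the hydration-layer increment applied.

    Beads whose neighbour count within ``_BURIAL_RADIUS`` falls below the
    burial threshold are treated as solvent-exposed and have their weight
    multiplied by (1 + _HYDRATION_GAIN * rho_hydration); buried beads are
    unchanged.  A single-bead structure is fully exposed.
    """
    xyz = structure.coords
    n = len(xyz)
    if n == 1:
        exposed = np.array([True])
    else:
        d = squareform(pdist(xyz)) < _BURIAL_RADIUS
        neighbors = d.sum(axis=1) - 1
        exposed = neighbors < _BURIAL_NEIGHBORS
    w = structure.weights.copy()
    w[exposed] *= 1.0 + _HYDRATION_GAIN * rho_hydration
    return w


def debye_intensity(
    structure: BeadStructure,
    q_grid,
    params: ScatterFitParams | None = None,
) -> SAXSCurve:
    """Debye sum over bead pairs.

    I(q) = scale * [sum_i w_i^2 + 2 sum_{i<j} w_i w_j sinc(q r_ij)]
    + background, with hydration-adjusted weights.  Invariant under rigid
    transformation of the whole structure; I(0) = scale*(sum w)^2 + bg.
    """
    params = params or ScatterFitParams(scale=1.0, rho_hydration=0.2, background=0.0)
    q = np.asarray(q_grid, dtype=float)
    w = effective_weights(structure, params.rho_hydration)
    form = _debye_form_factor(structure.coords, w, q)
    return SAXSCurve(q=q, I=params.scale * form + params.background)


def _debye_form_factor(xyz: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    """sum_ij w_i w_j sinc(q r_ij) for all q (vectorised over pairs)."""
    n = len(xyz)
    diag = float(np.sum(w**2))
    if n == 1:
        return np.full(q.shape, diag)
    d = pdist(xyz)
    iu, ju = np.triu_indices(n, k=1)
    ww = w[iu] * w[ju]
    out = np.empty(q.shape)
    # block over q to bound the (n_q x n_pairs) sinc workspace
    block = max(1, int(2**24 // max(d.size, 1)))
    for k0 in range(0, q.size, block):
        qb = q[k0 : k0 + block]
        out[k0 : k0 + block] = np.sinc(np.outer(qb, d) / np.pi) @ ww
    return diag + 2.0 * out


def guinier_fit(curve: SAXSCurve, qmax_rg: float = 1.3):
    """Guinier analysis: ln I vs q^2 on a self-consistent low-q window.

    Iterates the window q*Rg < qmax_rg to self-consistency; returns
    (Rg in A, I0, FitResult).  Upward curvature at the lowest q beyond a
    soft threshold sets ``fit.message`` to an aggregation warning.
    """
    q, I = curve.q, curve.I
    pos = I > 0
    q, I = q[pos], I[pos]
    if q.size < 5:
        raise ValueError("need at least 5 positive-intensity points")
    n_win = q.size
    rg = None
    for _ in range(50):
        qw, Iw = q[:n_win], I[:n_win]
        res = linear_fit(qw**2, np.log(Iw))
        slope = res["slope"]
        if slope >= 0:
            n_win = max(5, n_win // 2)
            continue
        rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(q, qmax_rg / rg))
        n_new = max(5, min(n_new, q.size))
        if n_new == n_win:
            break
        n_win = n_new
    if rg is None:
        raise ValueError("no Guinier region found (intensity not decaying)")
    i0 = float(np.exp(res["intercept"]))
    # upward curvature at lowest q signals aggregation: the apparent Rg
    # from the low half of the window runs well above the window value
    if n_win >= 10:
        half_n = n_win // 2
        res_low = linear_fit(q[:half_n] ** 2, np.log(I[:half_n]))
        if res_low["slope"] < 0:
            rg_low = float(np.sqrt(-3.0 * res_low["slope"]))
            if rg_low > 1.1 * rg:
                res.message = "aggregation warning: upward curvature at low q"
    rg_se = (
        1.5 * res.stderr("slope") / rg if np.isfinite(res.stderr("slope")) else np.inf
    )
    res.param_estimates.update({"Rg": rg, "I0": i0})
    res.param_uncertainties.update({"Rg": rg_se, "I0": i0 * res.stderr("intercept")})
    return rg, i0, res


def pr_invert(
    curve: SAXSCurve,
    Dmax: float,
    alpha: float = 1e-2,
    n_r: int = 101,
) -> PrResult:
    """Indirect Fourier transformation to the pair-distance distribution.

    Solves I(q) = 4*pi * integral p(r) sinc(qr) dr on a fixed r-grid by
    non-negative least squares with a second-difference smoothness
    penalty of weight ``alpha`` (Glatter-style regularization); p(0) and
    p(Dmax) are pinned to zero.  Rg and I(0) follow from the moments of
    p(r): Rg^2 = int r^2 p dr / (2 int p dr).
    """
    if Dmax <= 0:
        raise ValueError("Dmax must be positive")
    q, I = curve.q, curve.I
    sig = curve.sigma if curve.sigma is not None else np.full_like(I, max(I.max(), 1e-30) * 1e-2)
    r = np.linspace(0.0, Dmax, n_r)
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    K = 4.0 * np.pi * dr * np.sinc(qr / np.pi)
    # boundary pins: drop the first and last basis functions
    inner = slice(1, n_r - 1)
    A = K[:, inner] / sig[:, None]
    b = I / sig
    m = n_r - 2
    D2 = np.zeros((m, m))
    for i in range(m):
        D2[i, i] = -2.0
        if i > 0:
            D2[i, i - 1] = 1.0
        if i < m - 1:
            D2[i, i + 1] = 1.0
    scale = np.linalg.norm(A) / max(np.linalg.norm(D2), 1e-30)
    A_full = np.vstack([A, alpha * scale * D2])
    b_full = np.concatenate([b, np.zeros(m)])
    sol, _ = nnls(A_full, b_full)
    pr = np.zeros(n_r)
    pr[inner] = sol
    total = float(np.sum(pr) * dr)
    if total > 0:
        rg = float(np.sqrt(np.sum(r**2 * pr) * dr / (2.0 * total)))
        i0 = float(4.0 * np.pi * total)
    else:
        rg, i0 = 0.0, 0.0
    resid = (I - K @ pr) / sig
    # a trend in the residuals indicates Dmax truncation
    flagged = bool(abs(np.corrcoef(q, resid)[0, 1]) > 0.5) if np.std(resid) > 1e-12 else False
    return PrResult(r=r, pr=pr, Dmax=Dmax, Rg=rg, I0=i0, flagged=flagged)


def mass_from_i0(inputs: MassInputs, monomer_mass: float | None = None):
    """Molar mass from forward intensity: M = I0*NA/(c*drho_m^2) in g/mol.

    With ``monomer_mass`` (g/mol) also returns the monomer count
    M/monomer_mass rounded to one decimal.
    """
    M = inputs.I0 * inputs.NA / (inputs.c * inputs.drho_m**2)
    if monomer_mass is None:
        return M
    return M, round(M / monomer_mass, 1)


def q_window_summary(
    curve: SAXSCurve,
    low_window: tuple[float, float] = (0.01, 0.025),
    mid_window: tuple[float, float] = (0.07, 0.20),
    background: float = 0.0,
):
    """Mean background-subtracted intensity in the low-q and mid-q windows.

    The low-q metric tracks particle mass; the mid-q metric tracks
    tertiary-structure contrast.
    """
    out = []
    for lo, hi in (low_window, mid_window):
        mask = (curve.q >= lo) & (curve.q <= hi)
        if not np.any(mask):
            raise ValueError(f"window [{lo}, {hi}] contains no data points")
        out.append(float(np.mean(curve.I[mask] - background)))
    return tuple(out)


def _profile_scale_background(form: np.ndarray, I: np.ndarray, sig: np.ndarray):
    """Analytic weighted LSQ of I ~ scale*form + background (scale > 0)."""
    w = 1.0 / sig**2
    S = np.sum(w)
    Sf = np.sum(w * form)
    Sff = np.sum(w * form**2)
    SI = np.sum(w * I)
    SfI = np.sum(w * form * I)
    det = S * Sff - Sf**2
    if det <= 0:
        return max(SI / max(Sf, 1e-300), 1e-300), 0.0
    scale = (S * SfI - Sf * SI) / det
    bg = (Sff * SI - Sf * SfI) / det
    if scale <= 0:
        scale = max(SfI / Sff, 1e-300)
        bg = 0.0
    return float(scale), float(bg)


def _reduced_chi2(model_I: np.ndarray, I: np.ndarray, sig: np.ndarray, n_params: int = 3):
    dof = max(I.size - n_params, 1)
    return float(np.sum(((I - model_I) / sig) ** 2) / dof)


def chi2_fit(
    structure: BeadStructure,
    curve: SAXSCurve,
    rho_bounds: tuple[float, float] = (0.2, 1.3),
) -> tuple[ScatterFitParams, float]:
    """Fit scale, hydration and constant background by reduced chi^2.

    Scale and background are profiled analytically (they enter linearly);
    the hydration weight is optimised by bounded scalar minimisation.
    The reduced chi^2 uses N_q - 3 degrees of freedom.  A curve without
    uncertainties is fitted unweighted with a warning on the result.
    """
    if curve.sigma is None:
        import warnings

        warnings.warn("curve has no sigma; chi2 fit is unweighted")
        sig = np.ones_like(curve.I)
    else:
        sig = curve.sigma

    def objective(rho: float) -> float:
        w = effective_weights(structure, rho)
        form = _debye_form_factor(structure.coords, w, curve.q)
        scale, bg = _profile_scale_background(form, curve.I, sig)
        return _reduced_chi2(scale * form + bg, curve.I, sig)

    res = minimize_scalar(objective, bounds=rho_bounds, method="bounded")
    rho = float(res.x)
    w = effective_weights(structure, rho)
    form = _debye_form_factor(structure.coords, w, curve.q)
    scale, bg = _profile_scale_background(form, curve.I, sig)
    chi2 = _reduced_chi2(scale * form + bg, curve.I, sig)
    return ScatterFitParams(scale=scale, rho_hydration=rho, background=bg), chi2


# --- rigid-body Monte Carlo refinement ------------------------------------

def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _mc_objective(
    coords: np.ndarray,
    structure: BeadStructure,
    curve: SAXSCurve,
    sig: np.ndarray,
    cfg: MCConfig,
    w_eff: np.ndarray,
) -> tuple[float, float]:
    """(objective, reduced chi^2) for a candidate coordinate set."""
    form = _debye_form_factor(coords, w_eff, curve.q)
    scale, bg = _profile_scale_background(form, curve.I, sig)
    chi2 = _reduced_chi2(scale * form + bg, curve.I, sig)
    penalty = 0.0
    for i, j in cfg.anchors:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        penalty += cfg.spring_weight * max(0.0, d - cfg.rest_length) ** 2
    if cfg.clash_weight > 0:
        parts = structure.parts
        d = squareform(pdist(coords))
        inter = parts[:, None] != parts[None, :]
        clashes = int(np.sum((d < cfg.clash_cutoff) & inter) // 2)
        penalty += cfg.clash_weight * clashes
    return chi2 + penalty, chi2


def rigid_body_mc(
    structure: BeadStructure,
    curve: SAXSCurve,
    cfg: MCConfig,
    rho_hydration: float | None = None,
):
    """Three-part rigid-body Metropolis refinement against a SAXS curve.

    Each step picks one part uniformly, proposes a random rotation
    (uniform axis, angle ~ U(0, max)) about the part centroid plus a
    uniform translation, profiles scale and background analytically, and
    accepts by the Metropolis rule at fixed temperature on the objective
    reduced chi^2 + spring * sum max(0, d - rest)^2 + clash_weight *
    n_interpart_clashes.  The hydration weight is held at its initial
    chi^2-fit value during the walk.  Runs ``cfg.n_runs`` independent
    seeded walks; returns (best structure overall, per-run best chi^2
    array, per-run acceptance traces).
    """
    if structure.parts is None:
        raise ValueError("structure must carry part labels")
    part_ids = np.unique(structure.parts)
    if len(part_ids) < 2:
        raise ValueError("need at least two rigid parts")
    for i, j in cfg.anchors:
        if structure.parts[i] == structure.parts[j]:
            raise ValueError("anchors must connect different parts")
    if curve.sigma is None:
        raise ValueError("refinement requires per-point uncertainties")
    sig = curve.sigma

    if rho_hydration is None:
        fit0, _ = chi2_fit(structure, curve)
        rho_hydration = fit0.rho_hydration
    # hydration weights frozen at the starting exposure pattern
    w_eff = effective_weights(structure, rho_hydration)

    best_overall = None
    best_chi2_per_run = []
    traces = []
    for run in range(cfg.n_runs):
        rng = np.random.default_rng((cfg.seed, run))
        coords = structure.coords.copy()
        obj, chi2 = _mc_objective(coords, structure, curve, sig, cfg, w_eff)
        best_obj, best_coords, best_chi2 = obj, coords.copy(), chi2
        trace = [obj]
        for _ in range(cfg.n_steps):
            pid = part_ids[rng.integers(len(part_ids))]
            mask = structure.parts == pid
            Rm = _random_rotation(rng, cfg.max_rotation_deg)
            t = rng.uniform(-cfg.max_translation, cfg.max_translation, size=3)
            cand = coords.copy()
            center = cand[mask].mean(axis=0)
            cand[mask] = (cand[mask] - center) @ Rm.T + center + t
            cand_obj, cand_chi2 = _mc_objective(cand, structure, curve, sig, cfg, w_eff)
            accept = cand_obj <= obj
            if not accept and not cfg.greedy:
                accept = rng.random() < np.exp((obj - cand_obj) / cfg.temperature)
            if accept:
                coords, obj, chi2 = cand, cand_obj, cand_chi2
                if obj < best_obj:
                    best_obj, best_coords, best_chi2 = obj, coords.copy(), chi2
            trace.append(obj)
        best_chi2_per_run.append(best_chi2)
        traces.append(np.asarray(trace))
        if best_overall is None or best_obj < best_overall[0]:
            best_overall = (best_obj, best_coords)

    refined = replace(structure, coords=best_overall[1])
    return refined, np.asarray(best_chi2_per_run), traces


def superpose_rmsd(A: BeadStructure, B: BeadStructure) -> float:
    """RMSD after optimal least-squares (Kabsch) superposition of B on A."""
    if len(A) != len(B):
        raise ValueError("structures must have equal bead counts")
    X = A.coords - A.coords.mean(axis=0)
    Y = B.coords - B.coords.mean(axis=0)
    H = Y.T @ X
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, 1.0, d])
    R = U @ S @ Vt
    Yr = Y @ R
    return float(np.sqrt(np.mean(np.sum((X - Yr) ** 2, axis=1))))
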