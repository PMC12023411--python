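"""Seeded synthetic-data generators.

Each generator evaluates the corresponding forward model of the package
on a declared design and adds seeded Gaussian noise, so the whole
analysis chain is testable without any external data.  Defaults are the
study conditions: the wild-type FIDA titration spans 0.032-33.5 uM with
Rh endpoints 4.3/5.8 nm and KD 0.23 uM; the DSF-vs-concentration
titration uses Tm endpoints 35.2/40.9 degC with an apparent KD of
0.15 uM; denaturation presets use the 0.66 M activity midpoint and the
0.6/4.0 M double transition; thermal presets use the 23.3/34.0 degC
(cold-active) and 53.6 degC (mesophilic reference) midpoints; the Eyring
preset uses dH = 8.03 kcal/mol, dS = 25.0 cal/(mol K).  Noise defaults
are 2-3% of the dynamic range.  Every generator embeds its generating
spec in the returned object's metadata and is byte-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from .fida import Instrument, Species, SpeciesMix, Taylorgram, taylorgram_simulate
from .fitting import TitrationSeries
from .kinetics import (
    ActivationParams,
    BiphasicParams,
    MgActivationParams,
    biphasic_rate,
    eyring_rate,
    mg_activation_rate,
)
from .oligomer import AssociationParams, association_observable
from .saxs import BeadStructure, SAXSCurve, ScatterFitParams, debye_intensity
from .stability import (
    ThermalTransition,
    ThreeStateParams,
    TwoStateParams,
    thermal_signal,
    three_state_signal,
    two_state_signal,
)
from .evofit import ALPHABET, AMINO_ACIDS, MSA

__all__ = [
    "GeneratorSpec",
    "gen_association_titration",
    "gen_denaturation",
    "gen_thermal",
    "gen_kinetics",
    "gen_bead_dimer",
    "gen_msa",
    "gen_taylorgram",
    "PRESETS",
]


@dataclass
class GeneratorSpec:
    """Identity + parameters + design + noise + seed of one generation."""

    generator: str
    params: dict[str, Any] = field(default_factory=dict)
    design: dict[str, Any] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


# --- titration-series generators ------------------------------------------

def gen_association_titration(
    params: AssociationParams | None = None,
    m0_min: float = 0.032e-6,
    m0_max: float = 33.5e-6,
    n_points: int = 12,
    noise_sd: float | None = None,
    seed: int = 0,
) -> TitrationSeries:
    """Observable-vs-concentration titration under the dimer model.

    Default design mirrors the wild-type FIDA experiment: 12 log-spaced
    total concentrations from 0.032 to 33.5 uM, KD = 0.23 uM, Rh
    endpoints 4.3 and 5.8 nm.  ``noise_sd`` defaults to 2% of the
    endpoint span when not given explicitly; pass 0 for noiseless data.
    """
    params = params or AssociationParams(KD=0.23e-6, obs_mono=4.3, obs_dimer=5.8)
    if noise_sd is None:
        noise_sd = 0.02 * abs(params.obs_dimer - params.obs_mono)
    M0 = np.logspace(np.log10(m0_min), np.log10(m0_max), n_points)
    y = association_observable(M0, params)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    spec = GeneratorSpec(
        "association_titration",
        params={"KD": params.KD, "obs_mono": params.obs_mono, "obs_dimer": params.obs_dimer},
        design={"m0_min": m0_min, "m0_max": m0_max, "n_points": n_points},
        noise_sd=noise_sd,
        seed=seed,
    )
    sigma = np.full_like(y, noise_sd) if noise_sd > 0 else None
    return TitrationSeries(M0, y, sigma, axis="concentration", meta={"spec": spec.as_dict()})


#: cold-active three-state urea presets: activity midpoint 0.66 M,
#: structural double transition at ~0.6 and ~4 M.
_TWO_STATE_PRESET = TwoStateParams(
    alpha_N=1.0, beta_N=0.0, alpha_D=0.0, beta_D=0.0, m_DN=3.0 * 1.0, u50=0.66, RT=1.0
)
_THREE_STATE_PRESET = ThreeStateParams(
    alpha_N=1.0, beta_N=0.0, alpha_I=0.5, beta_I=0.0, alpha_D=0.0, beta_D=0.0,
    m_IN=3.0, m_DI=3.0, u50_I=0.6, u50_D=4.0, RT=1.0,
)


def gen_denaturation(
    params: TwoStateParams | ThreeStateParams | None = None,
    states: int = 2,
    u_max: float = 8.0,
    n_points: int = 25,
    noise_sd: float | None = None,
    seed: int = 0,
) -> TitrationSeries:
    """Urea denaturation curve from the two- or three-state model."""
    if params is None:
        params = _TWO_STATE_PRESET if states == 2 else _THREE_STATE_PRESET
    u = np.linspace(0.0, u_max, n_points)
    if isinstance(params, ThreeStateParams):
        y = three_state_signal(u, params)
        span = abs(params.alpha_N - params.alpha_D)
    else:
        y = two_state_signal(u, params)
        span = abs(params.alpha_N - params.alpha_D)
    if noise_sd is None:
        noise_sd = 0.02 * span
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    spec = GeneratorSpec(
        "denaturation",
        params={k: float(v) for k, v in asdict(params).items()},
        design={"u_max": u_max, "n_points": n_points, "states": states},
        noise_sd=noise_sd,
        seed=seed,
    )
    sigma = np.full_like(y, noise_sd) if noise_sd > 0 else None
    return TitrationSeries(u, y, sigma, axis="denaturant", meta={"spec": spec.as_dict()})


#: far-UV CD thermal presets (K): cold-active double transition at
#: 23.3/34.0 degC; mesophilic reference single transition at 53.6 degC.
THERMAL_PRESETS = {
    "ailac-thermal": (
        [ThermalTransition(tm=296.45, dH_vH=80000.0), ThermalTransition(tm=307.15, dH_vH=120000.0)],
        [(1.0, 0.0), (0.6, 0.0), (0.0, 0.0)],
    ),
    "eclac-thermal": (
        [ThermalTransition(tm=326.75, dH_vH=150000.0)],
        [(1.0, 0.0), (0.0, 0.0)],
    ),
}


def gen_thermal(
    transitions: list[ThermalTransition] | None = None,
    baselines: list[tuple[float, float]] | None = None,
    preset: str | None = None,
    T_min: float = 278.15,
    T_max: float = 353.15,
    n_points: int = 151,
    noise_sd: float | None = None,
    seed: int = 0,
) -> TitrationSeries:
    """Thermal unfolding curve with one or two van 't Hoff transitions."""
    if preset is not None:
        transitions, baselines = THERMAL_PRESETS[preset]
    if transitions is None:
        transitions, baselines = THERMAL_PRESETS["ailac-thermal"]
    T = np.linspace(T_min, T_max, n_points)
    y = thermal_signal(T, transitions, baselines)
    span = float(np.ptp(y)) or 1.0
    if noise_sd is None:
        noise_sd = 0.02 * span
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    spec = GeneratorSpec(
        "thermal",
        params={
            "transitions": [(t.tm, t.dH_vH) for t in transitions],
            "baselines": list(map(tuple, baselines)),
        },
        design={"T_min": T_min, "T_max": T_max, "n_points": n_points},
        noise_sd=noise_sd,
        seed=seed,
    )
    sigma = np.full_like(y, noise_sd) if noise_sd > 0 else None
    return TitrationSeries(T, y, sigma, axis="temperature", meta={"spec": spec.as_dict()})


#: activation preset of the cold-active enzyme (cal/mol, cal/(mol K)).
EYRING_PRESET = ActivationParams(dH_act=8030.0, dS_act=25.0)


def gen_kinetics(
    model: str,
    params=None,
    x=None,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Initial-rate series from one of the rate laws.

    ``model`` is "biphasic" (rate vs substrate), "mg" (rate vs Mg2+) or
    "eyring" (rate vs temperature).  Noise is relative Gaussian
    (``noise_rel`` * signal).
    """
    if model == "biphasic":
        params = params or BiphasicParams(kcat1=10.0, kcat2=100.0, K1=1e-3, K2=1e-2)
        x = np.logspace(-5, -1, 12) if x is None else np.asarray(x, dtype=float)
        y = biphasic_rate(x, params)
        axis = "concentration"
    elif model == "mg":
        params = params or MgActivationParams(
            kcat_a=4.6, kcat_b=85.5, kcat_c=20.0, KA=1e-5, KB=1e-1
        )
        x = np.logspace(-7, 0, 15) if x is None else np.asarray(x, dtype=float)
        y = mg_activation_rate(x, params)
        axis = "concentration"
    elif model == "eyring":
        params = params or EYRING_PRESET
        x = np.array([283.15, 288.15, 293.15, 298.15]) if x is None else np.asarray(x, dtype=float)
        y = eyring_rate(x, params)
        axis = "temperature"
    else:
        raise ValueError(f"unknown kinetics model {model!r}")
    rng = np.random.default_rng(seed)
    if noise_rel > 0:
        y = y * (1.0 + rng.normal(0.0, noise_rel, size=y.shape))
    spec = GeneratorSpec(
        f"kinetics:{model}",
        params={k: float(v) for k, v in asdict(params).items()},
        design={"x": [float(v) for v in x]},
        noise_sd=noise_rel,
        seed=seed,
    )
    return TitrationSeries(x, y, None, axis=axis, meta={"spec": spec.as_dict()})


# --- structural generators -------------------------------------------------

def _sphere_grid(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    """Cubic-grid points inside a sphere (deterministic filling)."""
    n = int(np.ceil(radius / spacing))
    ax = np.arange(-n, n + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + center


def gen_bead_dimer(
    lobe_radius: float = 30.0,
    lobe_separation: float = 75.0,
    bead_spacing: float = 8.0,
    q_grid: np.ndarray | None = None,
    noise_a: float = 0.0,
    noise_b: float = 0.0,
    params: ScatterFitParams | None = None,
    seed: int = 0,
) -> tuple[BeadStructure, SAXSCurve]:
    """Elongated two-lobe dimer bead model plus its Debye curve.

    Two spherical lobes of beads (radius ``lobe_radius`` A) joined by a
    thin bridge, labelled as three rigid parts (lobe / bridge / lobe).
    The default geometry is calibrated so the Guinier Rg of the curve is
    ~43-44 A, the size of the dimeric enzyme.  Noise per point is
    sigma(q) = noise_a + noise_b * I(q); pass zeros for a noiseless
    curve (then the curve equals the forward model exactly, with sigma
    set for chi^2 use from the same formula floor of 1% I).
    """
    half = lobe_separation / 2.0
    lobeA = _sphere_grid(np.array([-half, 0.0, 0.0]), lobe_radius, bead_spacing)
    lobeB = _sphere_grid(np.array([half, 0.0, 0.0]), lobe_radius, bead_spacing)
    # bridge spans only the gap between the lobe surfaces so the three
    # parts start clash-free and within the loop-anchor rest length
    n_bridge = max(3, int((lobe_separation - 2 * lobe_radius) / bead_spacing) + 2)
    bx = np.linspace(-half + lobe_radius, half - lobe_radius, n_bridge)
    bridge = np.column_stack([bx, np.zeros_like(bx), np.zeros_like(bx)])
    coords = np.vstack([lobeA, bridge, lobeB])
    parts = np.concatenate(
        [np.zeros(len(lobeA), int), np.ones(len(bridge), int), np.full(len(lobeB), 2, int)]
    )
    structure = BeadStructure(coords=coords, parts=parts)

    if q_grid is None:
        q_grid = np.linspace(0.008, 0.30, 120)
    params = params or ScatterFitParams(scale=1e-6, rho_hydration=0.2, background=0.0)
    curve = debye_intensity(structure, q_grid, params)
    sigma = noise_a + noise_b * curve.I
    rng = np.random.default_rng(seed)
    I = curve.I.copy()
    if np.any(sigma > 0):
        I = I + rng.normal(0.0, 1.0, size=I.shape) * sigma
    else:
        sigma = 0.01 * curve.I  # floor so chi^2 fits stay weighted
    return structure, SAXSCurve(q=q_grid, I=I, sigma=sigma)


def gen_msa(
    n_seq: int = 300,
    length: int = 50,
    n_invariant: int = 10,
    n_conserved: int = 10,
    conserved_p: float = 0.9,
    gap_p: float = 0.05,
    n_duplicates: int = 0,
    seed: int = 0,
) -> MSA:
    """Synthetic family MSA from a column-profile model.

    Columns come in three entropy classes: invariant (one residue),
    conserved (one dominant residue with probability ``conserved_p``,
    the rest spread uniformly) and free (uniform over the 20 residues).
    Gaps are injected i.i.d. at rate ``gap_p`` in free columns only, and
    ``n_duplicates`` exact copies of the first sequence are appended to
    exercise the redundancy filter.  Column classes are recorded in the
    returned object via ``msa.meta``-style attributes on ids.
    """
    rng = np.random.default_rng(seed)
    classes = (["invariant"] * n_invariant + ["conserved"] * n_conserved
               + ["free"] * (length - n_invariant - n_conserved))
    consensus = rng.integers(0, 20, size=length)
    seqs = []
    for _ in range(n_seq):
        chars = []
        for j, cls in enumerate(classes):
            if cls == "invariant":
                k = consensus[j]
            elif cls == "conserved":
                if rng.random() < conserved_p:
                    k = consensus[j]
                else:
                    k = rng.integers(0, 20)
            else:
                if rng.random() < gap_p:
                    chars.append("-")
                    continue
                k = rng.integers(0, 20)
            chars.append(AMINO_ACIDS[k])
        seqs.append("".join(chars))
    for d in range(n_duplicates):
        seqs.append(seqs[0])
    msa = MSA(sequences=seqs)
    # consensus string with gap-free columns for mutation scoring
    msa.consensus = "".join(AMINO_ACIDS[k] for k in consensus)  # type: ignore[attr-defined]
    msa.column_classes = classes  # type: ignore[attr-defined]
    return msa


def gen_taylorgram(
    protein_rh: float = 4.3,
    label_rh: float = 0.6,
    protein_amp: float = 1.0,
    label_amp: float = 0.3,
    instrument: Instrument | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Taylorgram:
    """Two-species taylorgram: free label (0.6 nm) plus labelled protein."""
    mix = SpeciesMix(
        species=[
            Species(Rh=label_rh, amplitude=label_amp, fixed_rh=True),
            Species(Rh=protein_rh, amplitude=protein_amp),
        ]
    )
    return taylorgram_simulate(mix, instrument=instrument, noise_sd=noise_sd, seed=seed)


#: named study-condition presets for the CLI.
PRESETS = {
    "ailac-wt-fida": lambda seed=0: gen_association_titration(seed=seed),
    "ailac-dsf": lambda seed=0: gen_association_titration(
        AssociationParams(KD=0.15e-6, obs_mono=35.2, obs_dimer=40.9), seed=seed
    ),
    "eclac-thermal": lambda seed=0: gen_thermal(preset="eclac-thermal", seed=seed),
    "ailac-thermal": lambda seed=0: gen_thermal(preset="ailac-thermal", seed=seed),
    "ailac-eyring": lambda seed=0: gen_kinetics("eyring", seed=seed),
    "dimer-saxs": lambda seed=0: gen_bead_dimer(seed=seed),
    "toy-family": lambda seed=0: gen_msa(seed=seed),
    "ailac-urea": lambda seed=0: gen_denaturation(states=2, u_max=3.0, seed=seed),
}
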