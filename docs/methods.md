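# Methods

This note documents the models implemented in `coldzyme`, the
assumptions behind them, the defaults of the synthetic-data generators,
and the numerical choices made where the design was genuinely open.

## Units and conventions

Concentrations are mol/L internally (the CLI accepts mM/μM/nM
suffixes), temperatures Kelvin (°C at the CLI), coordinates and
scattering vectors Å and Å⁻¹, energies cal/mol with
R = 1.98720 cal/(mol·K). The scattering vector is the standard
q = 4π sin θ/λ.

## Kinetics

The chromogenic assay follows ONP release at 420 nm; only the
deprotonated phenolate absorbs, so the effective extinction is
ε(pH) = ε₀·10^(pH−pKa)/(1+10^(pH−pKa)) with ε₀ = 4600 M⁻¹cm⁻¹ and
pKa = 7.2. Note that evaluating this expression at pH 7.0 gives
1779.6 M⁻¹cm⁻¹, not the 1741 sometimes quoted for the same constants;
the implementation follows the formula.

The biphasic substrate dependence comes from sequential binding of two
substrate molecules (E + 2S ⇌ E:S ⇌ E:S₂, dissociation constants K₁ and
K₂), giving kobs = (kcat1 + kcat2·S/K₂)/(1 + K₁/S + S/K₂). The Mg²⁺
dependence is a three-state ladder over zero/one/two bound ions:
kobs = (kcat_a·K_A/[Mg] + kcat_b + kcat_c·[Mg]/K_B)/(K_A/[Mg] + 1 +
[Mg]/K_B). This is the unique rational function consistent with the
stated limits (kcat_a at zero Mg²⁺, kcat_c at saturation, a maximum
near kcat_b when K_A ≪ [Mg] ≪ K_B).

Eyring analysis regresses ln(k/T) on 1/T; the slope is −ΔH‡/R and the
intercept ln(κ·k_B/h) + ΔS‡/R. The transmission coefficient κ is fixed
at 1 by default (exposed as a parameter) because no independent
estimate of it exists for this system. Cold-active enzymes often show a
kink in the Eyring plot near room temperature; a two-segment fit with a
user-supplied breakpoint (default 300 K) handles this. The breakpoint
is user-supplied because no objective criterion selects it.

Ionic strength is computed as I = ½Σcᵢzᵢ² after speciating total
phosphate between H₂PO₄⁻ and HPO₄²⁻ at the stated pH with pKa₂ = 7.2
(configurable); the first and third phosphate ionisations are
negligible near neutrality and are ignored. Cations are counted at
their formal concentrations. For the PBS + 0.1 mM MgCl₂ assay buffer at
pH 7.0 this gives 159.8 mM ≈ 160 mM.

## Stability

Isothermal denaturation uses the base-10 exponent form
K = 10^(m(u−u₅₀)/RT) as printed in the classic two-state treatment with
linear native/denatured baselines; the m-value therefore carries a
log10 convention, and `m_value_to_natural` converts to the conventional
natural-log slope (×ln 10). The three-state extension adds an
intermediate baseline and a second transition with populations
1 : K₁ : K₁K₂; it reduces exactly to the two-state form when the second
midpoint is pushed to infinite denaturant. Three-state fits constrain
u₅₀(I) ≤ u₅₀(D) with a box at the midpoint of the initial guesses to
prevent label switching.

Thermal transitions use the two-state van 't Hoff form
K(T) = exp[−(ΔH_vH/R)(1/T − 1/tm)] with linear baselines (intercepts
referenced to 0 K), in place of the closed-source global-analysis
software used on the original instrument data; tm and the baselines are
the comparable outputs. The double transition is modelled sequentially
(N→I→D, populations 1 : K₁ : K₁K₂). Note that a sequential double
transition with two identical (tm, ΔH) steps is *not* algebraically a
single two-state sigmoid — the population ladder 1 : K : K² has no
two-state equivalent — so the degenerate limit that is checked is the
second transition pushed far above the measured range, where the model
collapses to the single-transition curve exactly.

DSF midpoints are read as the extremum of the first derivative of the
330/350 nm ratio, after Savitzky–Golay smoothing (window 11, order 3 by
default — the instrument vendor does not document its smoothing) with
parabolic refinement of the discrete peak. A scan whose derivative
shows no distinct peak returns a no-transition result rather than
raising.

Free energies of unfolding extrapolated to 0 M denaturant are
deliberately not a headline output: the cold-active enzyme's unfolding
is irreversible (≈15% fluorescence recovery on refolding), so the
fitted midpoints are operational stabilities, not equilibrium ΔG values.

## Self-association

The monomer–dimer equilibrium is solved exactly: with conservation
M + 2D = M₀ and K_D = M²/D, the physical root of the quadratic is
D = [(4M₀+K_D) − √((4M₀+K_D)² − 16M₀²)]/8, evaluated in the
cancellation-free form D = 2M₀²/(4M₀ + K_D + √(K_D² + 8K_DM₀)) so the
speciation stays accurate to ~1e-12 relative down to picomolar M₀. The
observable model interpolates linearly in the dimer fraction 2D/M₀
between monomer and dimer endpoints. The apparent-Tm titration reuses
the identical functional form with Tm endpoints; the thermodynamic
linkage of unfolding and dissociation is deliberately not modelled —
this matches the empirical treatment that produced the apparent K_D.

K_D is fitted as log10(K_D) with bounds [−12, −2] (mol/L), initialised
from the half-transition concentration of the titration. A titration
spanning fewer than two decades triggers a warning; a flat titration
leaves K_D at a bound with unusable uncertainties (the unidentifiable
flag).

The n-mer generalization solves M + n·Mⁿ/K = M₀ by bisection (the left
side is strictly increasing, so the root is unique; tolerance 1e-12
relative) and maps the assembled subunit fraction linearly between
endpoints. For the engineered variant that assembles preformed dimers
into tetramers, the natural parameterization is n = 2 with the dimer as
the associating unit; the 1→2 parameterization is equally available.

## SAXS

Coarse-graining is one bead per residue (Cα or centroid), uniform
weights. The forward model is the Debye sum
I(q) = scale·[Σwᵢ² + 2Σ_{i<j} wᵢwⱼ sinc(q rᵢⱼ)] + background. Hydration
is modelled as a single multiplicative weight increment
(1 + 0.1·ρ_hydration) on solvent-exposed beads, where a bead is exposed
when fewer than 11 neighbours lie within 7.3 Å; ρ_hydration is bounded
to [0.2, 1.3]. This preserves the fitted contract (concentration scale,
hydration contribution, constant background) of the original
unpublished fitting program while keeping the form-factor model simple
and fully documented. Scale and hydration are nearly collinear for
compact particles, so individual values of the two are reported but
only their combination is well determined; fits are assessed on χ².

Guinier analysis iterates the window q·Rg < 1.3 to self-consistency on
ln I vs q²; an apparent Rg from the low half of the window more than
10% above the window value raises an aggregation warning. p(r)
inversion solves the Fourier kernel by non-negative least squares with
a second-difference smoothness penalty (weight α, default 1e-2,
normalised by the kernel scale), p(0) = p(Dmax) = 0 pinned; Rg and I(0)
come from the moments. Mass follows M = I(0)·N_A/(c·Δρ_m²) with the
typical protein contrast Δρ_m = 2.0×10¹⁰ cm/g (c in g/cm³; a mg/mL
value is 10⁻³ of that). The q-window summaries default to
low-q = [0.01, 0.025] Å⁻¹ (mass-proportional) and
mid-q = [0.07, 0.20] Å⁻¹ (tertiary-structure-proportional); the exact
windows are configurable since no canonical choice exists.

The rigid-body refinement divides the structure into three parts moved
as rigid bodies. Each Monte Carlo step picks one part uniformly,
rotates it about its centroid by an angle ~ U(0, 5°) about a uniform
random axis and translates it by U(−2, 2 Å)³; scale and background are
re-fitted analytically at every step (they enter the model linearly),
while the hydration weight is held at its initial χ²-fit value, since
it is not linear in the model and is nearly degenerate with scale. The
objective is reduced χ² (N_q − 3 degrees of freedom) plus a one-sided
spring Σ max(0, d_anchor − d_rest)² on loop anchors between consecutive
parts and a penalty per inter-part bead pair closer than 3.5 Å.
Acceptance is Metropolis at a fixed temperature of 0.5 objective units
(greedy mode available). Defaults are 10 independent runs of 100 steps,
reported as per-run best χ² (mean ± sd across runs); with the seed
fixed the entire output is bit-stable.

## Taylor dispersion (FIDA)

In Taylor's limit a species of diffusion coefficient D elutes as a
Gaussian centred at the residence time t_R with variance
σ² = R_c²·t_R/(24D); D converts to hydrodynamic radius by
Stokes–Einstein, D = k_BT/(6πηR_h). The two-species model sums the free
label (R_h conventionally locked at 0.6 nm) and the labelled protein,
and fits the central 75% of the points around the signal apex — the
vendor's "75% of curve length" is interpreted as the central fraction,
configurable. The instrument constants are synthetic fixtures
(capillary radius 37.5 μm, residence time 180 s — plausible for a
commercial instrument, but not measured values), and the buffer
viscosity defaults to water via the three-coefficient Vogel equation
η = 0.02939·exp(507.88/(T − 149.3)) mPa·s, overridable.

The bead-model R_h predictor is the Kirkwood double-sum approximation
1/R_h = 1/(Na) + (1/N²)Σ_{i≠j} 1/rᵢⱼ, accurate to roughly 5–10%
against full bead-shell hydrodynamics. Denatured-chain sizes use the
empirical power law R_h = 2.21·N^0.57 Å.

## Evolutionary fitness

The family model is a variational autoencoder over one-hot encoded
alignments (20 amino acids + gap as its own symbol). Sequences with
more than 25% gaps are discarded, then redundancy is removed greedily
in input order (Hobohm-1 style): a sequence is kept only if its
identity (matches over mutually non-gap columns) to every kept sequence
is below 95%. Sequence weighting by inverse neighbourhood counts is off
by default and available as an option.

The VAE is implemented directly in numpy (MLP encoder and decoder, ReLU
activations, diagonal-Gaussian posterior, per-position softmax output,
full-batch Adam on the negative ELBO, one reparameterisation draw per
epoch). The scaled-down defaults — hidden sizes [64, 32]/[32, 64],
latent dimension 8, 200 epochs — are the test surface and train in
seconds on synthetic families of a few hundred sequences; a full-scale
family model (hidden sizes [2000, 1000, 300] mirrored, tens of
thousands of epochs, thousands of sequences) is accepted by the same
code but not required by any test. The latent dimension is configurable
because no canonical value exists for this family.

A mutation's evolutionary fitness score is
−[ELBÔ(mutant) − ELBÔ(wild type)], each ELBÔ an importance-weighted
estimate logmeanexp[log p(x|z) + log p(z) − log q(z|x)] over n
posterior samples (default 2000). Both sequences are scored with the
same random draws (common random numbers), which cancels most sampling
noise in the difference; the wild type against itself is exactly 0.
Lower scores mean fitter mutations. Only the ordering and the sign
convention are meaningful; absolute scores depend on the training
corpus and are not comparable across models.

Interface residues of a dimer are residue pairs across chains with any
heavy-atom distance below 5.5 Å (KD-tree search, verified against the
all-pairs brute force). Buried surface fraction uses Shrake–Rupley SASA
(≥ 960 points per atom, probe 1.4 Å, element-based radii) on the
complex versus the chains alone.

## Synthetic-data generators

Each generator evaluates the corresponding forward model on a declared
design and adds seeded Gaussian noise; the generating spec (parameters,
design, noise, seed) is embedded in the output metadata and survives
file round trips. Defaults are the study conditions:

- association titration: 12 log-spaced points, 0.032–33.5 μM,
  K_D = 0.23 μM, R_h endpoints 4.3/5.8 nm (apparent-Tm variant:
  K_D = 0.15 μM, endpoints 35.2/40.9 °C);
- urea denaturation: activity midpoint 0.66 M (two-state) and
  structural midpoints 0.6/4.0 M (three-state), m/RT = 3 per M;
- thermal scans: cold-active double transition 23.3/34.0 °C, mesophilic
  reference 53.6 °C; van 't Hoff enthalpies 80–150 kcal/mol, chosen as
  typical for cooperative transitions of a large multidomain protein;
- Eyring: ΔH‡ = 8.03 kcal/mol, ΔS‡ = 25.0 cal/(mol·K) at 283–298 K;
- bead dimer: two 30 Å lobes of grid beads 75 Å apart joined by a thin
  bridge, three labelled parts, geometry calibrated so the Guinier Rg
  is ≈ 44 Å (the dimeric enzyme); q-dependent noise σ(q) = a + b·I(q);
- MSA: column-profile model with invariant, conserved (dominant residue
  probability 0.9) and free columns, i.i.d. gaps in free columns, and
  optional exact duplicates for filter testing;
- taylorgram: 0.6 nm label + protein mixture on the fixture instrument.

Noise defaults are 2–3% of the dynamic range where a noisy curve is
requested; all quantitative-recovery tests use zero-noise generation.
Because the generators sample the same forward models the fitters
assume, passing recovery tests demonstrates correctness of the
estimation machinery, not robustness to the instrument artifacts
(detector smearing, capillary fouling, baseline drift, label
photophysics) that real data carry.

Two design facts about the default association titration are worth
noting: at 32 nM roughly 18% of subunits are already dimeric with
K_D = 0.23 μM, and at 33.5 μM about 6% remain monomeric, so the grid
extremes approach but do not reach the endpoint observables; the
endpoints are properly recovered only by fitting the model.

## Numerical choices and degenerate inputs

- Nonlinear fits go through one engine (trust-region least squares via
  lmfit, numerical Jacobians, deterministic); non-convergence and
  singular Jacobians are flagged on the result, not raised. The
  biphasic rate law's loss surface can be multimodal when the two
  phases overlap, so a seeded 10-start option jitters the initial K's.
- Rate laws return their analytic limits at zero concentration rather
  than dividing by zero.
- Exponents in the denaturation and van 't Hoff equilibria are clipped
  at ±300 in log-space to avoid overflow without affecting any
  realistic parameter range.
- The Debye sum is evaluated in q-blocks bounded to ~16M pair-q entries
  so large bead models do not exhaust memory.
- Problem sizes used in the test suite (bead models of ~150–450 beads,
  80–150 q points, MSAs of 200–1000 sequences × 40–60 columns,
  100-step/10-run refinements) were chosen so each check runs in
  seconds while leaving the conclusions unchanged at larger scale.

## Known limitations

- The SAXS hydration model is a binary exposure increment, not a
  physical hydration shell; absolute hydration values are not
  interpretable, only the fitted curve is.
- No explicit-atom form factors, excluded-volume solvent term, or
  interparticle structure factors; absolute-scale calibration against
  water is out of scope.
- The taylorgram model omits adsorption, labelling stoichiometry and
  photobleaching.
- The association models are equilibrium-only (no kinetics, no
  heteroassociation, no linked folding–binding polynomial).
- Evolutionary fitness scores from the scaled-down VAE on synthetic
  families demonstrate the scoring machinery; biological conclusions
  require a real family alignment at full scale.
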