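# coldzyme

Biophysical analysis toolkit for a cold-active, dimer-forming GH2
β-galactosidase (a psychrophilic lactase) and its engineered
tetramer-forming variants. The package reimplements, as tested and
reusable code, the quantitative analysis chain used to characterise such
an enzyme:

- **Enzyme kinetics** — pH-dependent ONP extinction, specific activity
  (U/mg) from absorbance slopes, a biphasic sequential two-site
  substrate-binding rate law, a two-site Mg²⁺ activation ladder, and
  Eyring analysis of kcat(T) (`coldzyme.kinetics`).
- **Stability** — two- and three-state isothermal urea denaturation with
  linear baselines (base-10 exponent convention), van 't Hoff thermal
  transitions (single and sequential double), DSF inflection-point
  extraction, sigmoid aggregation midpoints, cosolute stabilization
  slopes (`coldzyme.stability`).
- **Self-association** — exact monomer–dimer speciation, observable
  mapping for hydrodynamic radius and apparent Tm, KD estimation in
  log-space, and an n-mer generalization for dimer → tetramer assembly
  (`coldzyme.oligomer`).
- **SAXS** — residue-bead Debye forward scattering with a hydration
  term, Guinier analysis, regularized p(r) inversion, I(0) mass
  estimates, q-window summaries, χ² fitting, and three-part rigid-body
  Metropolis Monte Carlo refinement (`coldzyme.saxs`).
- **FIDA / Taylor dispersion** — taylorgram forward model, two-species
  fitting with a locked free-label radius, Stokes–Einstein conversion,
  and a Kirkwood bead-model Rh predictor (`coldzyme.fida`).
- **Evolutionary fitness** — MSA gap/redundancy filtering, a compact
  numpy variational autoencoder over protein families, ELBO-based
  mutation scoring (lower = fitter), interface-contact selection at a
  5.5 Å heavy-atom cutoff, and interface mutation ranking
  (`coldzyme.evofit`).
- **Synthetic data** — seeded generators that emulate every input the
  analysis chain consumes, so the whole pipeline runs with no downloads
  (`coldzyme.synthetic`).

## The models at the core

Self-association maps the dimer fraction onto any observable:

    obs(M₀) = obs_mono + (2[D]/[M₀]) · (obs_dimer − obs_mono),
    [D] = [(4M₀ + K_D) − √((4M₀+K_D)² − 16M₀²)] / 8,

where M₀ is the total monomer-equivalent concentration and K_D the
dimer dissociation constant. The Eyring regression is

    ln(kcat/T) = −ΔH‡/R · 1/T + ln(κ k_B/h) + ΔS‡/R   (κ = 1),

and the two-state denaturation signal with linear baselines is

    S(u) = [αN + βN u + (αD + βD u)·K] / (1 + K),
    K = 10^{m(u − u₅₀)/RT}.

The SAXS forward model is a Debye sum over residue beads,
I(q) = scale·Σᵢⱼ wᵢwⱼ sinc(q rᵢⱼ) + background, with a hydration
increment on solvent-exposed beads; the refinement walks three rigid
parts under a profile-χ² objective with loop restraints and clash
penalties.

## Worked example

```python
import numpy as np
from coldzyme import oligomer, synthetic

# noiseless synthetic Rh titration at the wild-type study conditions:
# 12 log-spaced concentrations 0.032-33.5 uM, KD 0.23 uM, 4.3/5.8 nm
series = synthetic.gen_association_titration(noise_sd=0.0)
fitted, result = oligomer.fit_association(series)
print(f"KD = {fitted.KD * 1e6:.2f} uM")
print(f"monomer Rh = {fitted.obs_mono:.1f} nm, dimer Rh = {fitted.obs_dimer:.1f} nm")
```

prints

```
KD = 0.23 uM
monomer Rh = 4.3 nm, dimer Rh = 5.8 nm
```

i.e. the fit recovers the dissociation constant of the monomer–dimer
equilibrium and both endpoint radii from the titration alone. The same
functional form fitted to melting temperatures versus concentration
yields the apparent K_D ≈ 0.15 μM that links dimerization to thermal
stabilization.

The CLI exposes the same operations, e.g.

```
coldzyme synth --preset ailac-wt-fida --seed 1 --out titration.csv
coldzyme oligo fit --data titration.csv --out fit.json
```

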