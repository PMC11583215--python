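# saftgmie

A group-contribution equation of state for predicting the solubility of
amino acids and small peptides in water and alcohols, including its pH
dependence — aimed at formulation and crystallization work where measuring
every solute/solvent/pH combination is impractical.

Molecules are built from transferable functional groups (H2O, COOH, NH2,
CH3, CH2, CH, CH2OH, CHOH, CONH, and the charged COO⁻, NH3⁺, H3O⁺, OH⁻,
Na⁺, Cl⁻), each a set of ν\* fused spherical Mie segments of diameter σ,
dispersion energy ε/k_B, and variable repulsive range λʳ, contributing with
a fractional shape factor S. The Helmholtz free energy of a mixture is

    A = A_ideal + A_mono + A_chain + A_assoc + A_ion + A_Born

where `A_mono` is a third-order Barker–Henderson perturbation expansion
about a hard-sphere reference (Boublík mixture free energy with effective
diameters d(T)), `A_chain` is the first-order Wertheim (TPT1) connectivity
correction evaluated with the contact value of the Mie radial distribution
function of a molecularly averaged fluid, and `A_assoc` is the Wertheim
association term for embedded H/e1/e2 hydrogen-bonding sites with strengths
Δ = [exp(ε^HB/kT) − 1]·K^HB·I(ρ\*, T\*). For mixtures with net-charged
species, `A_ion` is the mean-spherical-approximation Coulomb term with its
implicitly solved screening parameter Γ (→ κ_D/2 at high dilution), and
`A_Born` the classical charging energy of each ionic cavity in a medium of
relative permittivity D(T, ρ_solv). Non-spherical ions map onto
equal-volume spheres group-wise (Model G, default) or molecule-wise
(Model M); zwitterions contribute nothing electrostatic.

On top of the free energy the package solves:

- **Solid–liquid equilibrium**:
  `ln(x γ) = −(Δh_fus/R)(1/T − 1/T_fus) + (Δcp/R)(T_fus/T − 1 − ln(T_fus/T))`
  with γ the symmetric activity coefficient from the model.
- **Acid–base speciation** of diprotic amino acids (cation/zwitterion/anion
  with H3O⁺, OH⁻ and Na⁺/Cl⁻ counterions), with activity-based equilibrium
  constants, van 't Hoff temperature corrections, pH = −log10 a(H3O⁺),
  titration curves, and pH-resolved solubility where only the zwitterion is
  equated with the pure solid.

All group parameters, melting properties and acid–base constants ship as
CSV tables under `src/saftgmie/data/`.

## Worked example

```python
from saftgmie import (GammaMieEoS, MeltingProperties, amino_acid,
                      ideal_solubility, solve_sle, water)

eos = GammaMieEoS([water(), amino_acid("glycine")])
mp = MeltingProperties.from_table("glycine")   # T_fus = 569 K, 22 kJ/mol
res = solve_sle(eos, 298.15, 1e5, [1.0, 0.0], 1, mp)
print(ideal_solubility(298.15, mp), res.x_sat, res.gamma_at_sat)
```

prints

```
0.014632636037877188 0.0007829775645534244 18.691841
```

i.e. the ideal (γ = 1) solubility from the melting properties alone is
x = 0.0146; with the full activity model the saturated mole fraction drops
to 7.8e-4 because the model assigns the glycine melt a strongly positive
deviation from ideality in water (γ ≈ 18.7 at saturation). The
`examples/` directory contains short narrative scripts for each
capability: pure-water properties, amino-acid solubility, titration and
speciation, pH-resolved solubility, and the electrolyte terms; each prints
the quantities it computes together with a line on how to read them.

A thin CLI mirrors the library for batch runs
(`saftgmie run --config cfg.yaml`, tasks: density, activity, sle, bubble,
titrate, solubility-vs-ph; `saftgmie make-fixture` writes toy parameter
sets with closed-form behavior).

## Scope and limitations

Group-parameter regression is out of scope: all interaction parameters are
tabulated inputs. Only diprotic (non-ionizable side chain) amino acids are
speciated. See `docs/methods.md` for the model assumptions, numerical
choices, and known limitations — including a documented systematic
overestimation of aqueous activity coefficients of large nonpolar solutes.
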