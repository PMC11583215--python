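# Methods

## Model

Molecules are heteronuclear chains of fused spherical segments. A group
`k` consists of ν\*_k identical segments of diameter σ_kk (Å) interacting
through Mie potentials u(r) = C ε [(σ/r)^λr − (σ/r)^λa] with
C = λr/(λr−λa)·(λr/λa)^{λa/(λr−λa)}; its contribution to a molecule's free
energy is scaled by the shape factor S_k ∈ (0, 1.5]. The attractive
exponent is λa = 6 for every packaged group. Hydrogen bonding is mediated
by embedded sites of types H, e1, e2.

The Helmholtz energy is the sum A = A_ideal + A_mono + A_chain + A_assoc
(+ A_ion + A_Born when net-charged species are present).

**Ideal term.** a_ideal = Σ x_i ln(ρ_i Λ³) − 1 with the de Broglie volume
set to Λ³ = 1 m³. This shifts chemical potentials by temperature-dependent
constants that are identical in coexisting phases and cancel from every
phase- and chemical-equilibrium computation here; for the acid–base
reactions the constants are absorbed in the empirical K(T).

**Monomer term.** Third-order Barker–Henderson high-temperature expansion,
a_mono = m̄ (a_HS + βa1 + β²a2 + β³a3) with m̄ = Σ x_i Σ_k ν_{ki} ν\*_k S_k
and segment fractions x_{s,k} ∝ x_i ν_{ki} ν\*_k S_k. The hard-sphere
reference is the Boublík mixture expression over temperature-dependent
diameters d_kk(T) = ∫₀^σ [1 − e^{−βu}] dr (fixed 100-point Gauss–Legendre;
the quadrature choice is free and this rule is converged to machine
precision for every packaged exponent). a1 uses the mean-value-theorem
correlation for the Sutherland kernels plus the d→σ correction term; a2 the
macroscopic-compressibility approximation with the fitted correction factor
(1+χ); a3 the fitted empirical form. Unlike pairs use σ_kl = (σ_kk+σ_ll)/2,
d_kl = (d_kk+d_ll)/2, ε_kl from the tables or the σ³-weighted geometric
combining rule, and λ_kl − 3 = √((λ_kk−3)(λ_ll−3)).

**Chain term.** a_chain = −Σ x_i (Σ_k ν_{ki} ν\*_k S_k − 1) ln g^Mie_ii,
with g^Mie evaluated at the averaged contact diameter of component i in a
hypothetical one-fluid of the mixture's packing fraction ζ_x. Molecular
averages use the segment-weight fractions z_{ki}: σ̄³ and d̄³ are
cubic-averaged, ε̄ and λ̄ linearly averaged. g^Mie = g_HS exp[(βε̄ g1 +
(βε̄)² g2)/g_HS] with the published first- and second-order perturbation
corrections (γ_c switch for g2).

**Association.** Wertheim TPT1: a_assoc = Σ x_i Σ_k ν_{ki} Σ_a n_{ka}
(ln X_{ka} + (1−X_{ka})/2). The mass-action system X = 1/(1 + Σ ρ_b X_b
Δ_ab) uses Δ_ab = [e^{ε^HB/kT} − 1] K^HB I(ρ\*, T\*), with the bonding
volume K^HB in Å3 from the tables, the dimensionless kernel I a
lower-triangular 11×11 polynomial in the reduced segment density
ρ\* = ρ_s σ̄_x³ and the pair reduced temperature T\* = kT/ε_kl. The solver
runs damped successive substitution (factor 0.5) into a log-variable Newton
with line search (tolerance 1e-12); X ≡ 1 exactly for sites without
partners.

**Electrostatics.** Charged groups enter the mean-spherical-approximation
ion term with the implicitly solved screening parameter Γ
(4Γ² = α² Σ ρ_e Q_e(Γ)², fixed point from the Debye start Γ₀ = κ_D/2,
tolerance 1e-12) and the classical Born charging energy with cavity radius
σ^Born/2. Only species with net charge contribute; zwitterions contribute
exactly zero. Non-spherical ions are mapped to equal-volume spheres either
per charged group (Model G, default, σ̃ = ν\*^{1/3} σ) or per molecule
(Model M); for monatomic ions the two coincide identically. The relative
permittivity D = 1 + ρ_solv Σ x'_i x'_j (d_ii + d_jj)/2,
d_ii = d_V (d_T/T − 1), uses salt-free solvent fractions; water's d_V =
588.02 Å3 and d_T = 1480.9 K were fitted in-package to the static
permittivity of liquid water at 273.15/298.15/373.15 K (87.90/78.41/55.58)
using this model's own liquid densities at 1 bar; the mid-point is
reproduced to 0.7%.

## Derived thermodynamics

Pressure and chemical potentials come from complex-step differentiation of
the residual Helmholtz energy (step 1e-100 relative; exact to machine
precision, no truncation/round-off trade-off). All solvers in the residual
path are transparent to complex arguments. Density roots at (T, P) are
located by a 200-point geometric scan up to segment packing 0.9 followed by
Brent refinement; among mechanically stable roots the lowest-Gibbs one is
returned unless a phase hint forces the densest/least dense.

Activity conventions: water (and solvents generally) symmetric,
γ_w = φ_w(x)/φ_w(pure); solutes asymmetric molality-based,
γ̃_{m,i} = x_solv φ_i(x)/φ_i(x^∞) and a_i = m_i γ̃/m⁰ with m⁰ = 1 mol/kg.
The infinite-dilution reference pins every non-solvent species at mole
fraction 1e-15 (solvents renormalized, counterions retained so the
reference state stays electroneutral) — a single well-defined reference
for all solutes simultaneously.

## Solid–liquid equilibrium

ln(x_sat γ) = −(Δh_fus/R)(1/T − 1/T_fus) + (Δcp/R)(T_fus/T − 1 −
ln(T_fus/T)), solid phase pure solute, γ symmetric against the subcooled
pure liquid at the same (T, P). The Δcp term uses the standard two-piece
constant-Δcp form and is included only when a Δcp value exists in the
melting table. The root is found on ln x (solubilities span many decades)
by bracket scan plus Brent; the solution is independent of the search
window.

## Speciation

Reactions: AA⁺ + H₂O ⇌ AA± + H₃O⁺ (K_A1), AA± + H₂O ⇌ AA⁻ + H₃O⁺ (K_A2),
2 H₂O ⇌ H₃O⁺ + OH⁻ (K_W, divided by a_w²), all written with activities;
pH = −log10 a(H₃O⁺). K(T) follows van 't Hoff, ln K(T) = ln K(T₀) +
(Δh/R)(1/T₀ − 1/T), the sign fixed by requiring the tabulated 298.15 K
constants to reproduce the known elevated-temperature pK values. Unknowns
are log-molalities (positivity by construction); Newton with line search
starts from the ideal closed form, and the charge balance is closed
algebraically by the appropriate counterion (NaOH raises pH, HCl lowers
it — the chemically consistent direction). The water activity is included
by default and can be pinned to 1 for comparison; with ideal activities and
a_w = 1 the solution matches the exact quartic proton polynomial to 1e-10.
pH-resolved solubility equates only the zwitterion with the solid and adds
the charged species through the equilibria; with ideal activities no finite
saturation exists at extreme pH (the anion/cation branch grows without
bound), which the solver reports as an infeasible target.

## Synthetic fixtures

`make_fixture` provides parameter sets whose behavior is known in closed
form: an exact ideal gas (σ = 0 removes every interaction), hard spheres
(ε = 0 keeps d = σ and removes attraction — a fixture convention, since the
Mie amplitude scales with ε), a bare 12-6 Mie fluid, the restricted
primitive model (equal-diameter ±1 ions in a structureless dielectric
solvent), and an ideal diprotic ampholyte. These exist to oracle-test the
machinery; they emulate no real system, so passing them validates the
mathematics, not the chemistry.

## Validation status and known limitations

Verified against independent oracles: hard-sphere term ≡
Carnahan–Starling/BMCSL (1e-16); a1 ≡ exact low-density quadrature and an
Ornstein–Zernike (Percus–Yevick) quadrature at liquid density (≤ 1.7%);
two-site association ≡ closed form (1e-12); MSA Γ ≡ restricted-primitive
closed form (1e-13) and the Debye–Hückel limits; Born ≡ classical charging
energy; Gibbs–Duhem residuals ≤ 1e-6; complex-step derivatives ≡ finite
differences. Physical anchors: liquid water 985.5 kg/m³ and p_sat 3.67 kPa
at 298.15 K; n-hexane p_sat 22.9 kPa at 298.15 K; the 12-6 Mie critical
temperature 1.34 ε/k.

Known limitation: aqueous activity coefficients of solutes with large
segment volumes come out systematically higher than the parameterization's
source data imply (e.g. hydrophobic solutes by several ln units), which
propagates to underpredicted aqueous solubilities for the more hydrophobic
amino acids. The effect scales with inserted segment volume and is
insensitive to every closed-form-verifiable term; it most likely resides in
fine coefficients of the fitted association-kernel/RDF-correction tables,
for which no independent reference was available. Predictions of trends
(temperature dependence, pH profiles, speciation) are unaffected in shape.

Out of scope by design: parameter regression, liquid–liquid equilibria,
polyprotic amino acids, polymorphism, intramolecular association, and
explicit-solvent electrostatics.

## Problem sizes

The test suite and the acceptance script run small, fixed problems: binary
or ternary mixtures, pH grids of a few dozen points, density scans of 200
points — each full solid–liquid equilibrium solve takes seconds on one
core, chosen to keep the whole suite under a few minutes.
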