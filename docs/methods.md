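# Methods

## Model and conventions

**Force field.** Potentials are sums of harmonic bonds ½k(r−r₀)², Morse
bonds D(1−e^{−a(r−r₀)})² (intended for X–H stretches, where zero-point
motion probes the anharmonic tail), harmonic angles, optional
cosine-series dihedrals, harmonic lab-frame tethers (validation systems
only), 12-6 Lennard-Jones with Waldman–Hagler σ⁶-mixing plus an analytic
isotropic tail correction, and real-space Coulomb electrostatics. Units:
kJ/mol, Å, ps, K, elementary charge, g/mol; masses are internally scaled
by 0.01 so kinetic energies come out in kJ/mol.

**Electrostatics.** There is no reciprocal-space mesh: the engine targets
boxes of tens of molecules, where a shifted-force real-space Coulomb
(energy and force continuous at the cutoff) is stable and adequate. The
cutoff defaults to min(14 Å, 0.40·L₀) at run start — the 0.40 factor
leaves the barostat ~20 % compression headroom before the minimum-image
auto-reject (box ≥ 2·r_c), so boxes should be initialized near their
equilibrium density. Every observables file records the cutoff and the
electrostatics scheme. A `coulomb="bare"` option provides plain truncated
1/r for reference calculations.

**Exclusions.** 1-2 and 1-3 nonbonded pairs are excluded; 1-4 pairs are
scaled by a configurable factor (default 0.5). The toy templates have no
1-4 pairs, so this choice is inert for the shipped studies.

**Path integral.** The sample-at-physical-temperature convention: bead
springs at ω_n = √P·k_BT/ħ, physical potential scaled by 1/P, thermostats
targeting the physical T. P = 1 reduces exactly to classical MD.
Integration is OBABO: half PILE Ornstein–Uhlenbeck (centroid friction
1 ps⁻¹ by default, internal mode k at γ_k = 2ω_k), half momentum kick,
*exact* free-ring-polymer normal-mode propagation (stable for stiff
springs at P = 32 and Δt = 0.5 fs), half kick, half thermostat. Gas-phase
mode uses an Andersen thermostat (collision frequency 10 ps⁻¹, interpreted
as a per-atom resampling rate) with net linear and centroid angular
momentum removal.

**Barostat.** Monte Carlo volume moves every 25 fs: uniform ΔV proposal,
rigid per-molecule displacement of the (centroid) center of mass —
intramolecular and intra-ring geometry untouched — accepted with
exp{−β[ΔŪ + PΔV − N_mol·k_BT·ln(V′/V)]}, Ū being the bead-averaged
potential. The N_mol logarithm term is the configurational Jacobian of
molecular scaling, exact for uniform-ΔV proposals; the ideal-gas test
asserts the implied stationary mean ⟨V⟩ = (N_mol+1)k_BT/P. The proposal
width adapts toward ~50 % acceptance only during the first 300 attempts
and is then frozen, preserving detailed balance over production
(continuous adaptation measurably biased ⟨V⟩ in the ideal-gas check).

**Kinetic-energy estimators.** Primitive: (3N·P/2)k_BT − E_spring.
Centroid-virial: (3N/2)k_BT − ½Σ_b(x_b−x̄)·f_b/P. Both are unbiased; the
centroid-virial has bead-count-independent variance and is the one used in
Δh_vap and in recorded energies. For harmonic systems the exact finite-P
expectations follow from the Gaussian bead covariance; the test-suite uses
that closed form as an independent oracle.

**Dielectric estimator.** The per-bead dipole-fluctuation formula averaged
over beads, exactly as defined above — not the full estimator with
cross-bead dipole correlations. The bead-resolved dipole series is stored,
so the alternative is one line of user code; at P = 1 both coincide with
the textbook classical formula. Box dipoles are assembled molecule-wise
from fixed point charges (no induced polarization), so they are invariant
under periodic wrapping for neutral molecules.

**Δh_vap.** Per-bead total internal energies (potential plus the
centroid-virial quantum kinetic energy divided per bead) per mole of
molecules in each phase; the two phases must share T and P (bead count).
Classically the kinetic terms cancel and the familiar −⟨U_l⟩/N + k_BT
emerges, which the tests assert.

**Isotope-effect sign convention.** Δ^{D→H} = (λ^H − λ^D)/λ^D
= λ^H/λ^D − 1. Some texts quote the equilibrium isotope effect with the
opposite sign (1 − λ^H/λ^D); only the sign differs, and this package uses
the first form everywhere.

## Study conditions (synthetic-data defaults)

**Toy liquids.** Three templates: a stiff X–H diatomic (X: 30 g/mol,
−0.24 e, σ 2.4 Å, ε 1.4 kJ/mol; H: 1.008 g/mol, +0.24 e, σ 2.2 Å,
ε 0.25 kJ/mol; k 3000 kJ/mol/Å², r₀ 0.95 Å), a bent water-like triatomic,
and a hydroxyl-headed 4-site chain. Molecules are packed with random
positions/orientations under a 1.6 Å inter-molecular clash limit;
deuteration substitutes 1.008 → 2.014 g/mol and nothing else.

The headline isotope study uses the diatomic at **150 K**, 1 atm, 32
molecules (box 8.7 Å), P = 32, Δt = 0.5 fs, with four independently
packed and seeded replicas per treatment (matching the reference
four-simulation replicate design). Path-integral legs: 1 ps NVT + 8 ps
NPT equilibration + 18 ps NPT production; the classical treatments, ~50×
cheaper per step, run 40 ps production instead — extra power where it
costs nothing, which sharpens the classical H/D invariance baseline (an
equivalence check that only gets harder to pass with better statistics).
The choice of 150 K rather than ambient
temperature is deliberate desk-scale design: the hydrogen thermal
wavelength scales as 1/√T, so cooling doubles the quantum swell of the H
sites (βħω ≈ 26 for the stretch; free-H ring-polymer radius ≈ 0.6 Å) and
lifts Δ_vm to ≈ 7 % and the H/D gap to ≈ 3.5 % — both an order of
magnitude above the ~0.5 % volume SEM attainable in minutes of sampling.
At 298 K the same contrasts are ~1 % against comparable noise, i.e. not
resolvable at this scale. The engine itself defaults to the ambient
protocol values (298.15 K setpoints, 1 ps⁻¹ friction, 25 fs barostat).

What the toy liquid emulates: a bound (≈6 k_BT/molecule), mobile molecular
liquid whose hydrogens are strongly quantum, where classical H/D
equilibrium averages coincide and quantum delocalization expands the
liquid, with deuteration intermediate. What it does not: real molecular
chemistry (dispersion/electrostatics balance, hydrogen-bond networks,
long-range electrostatics), system-size effects (dielectric and κ_T are
strongly finite-size affected at 32 molecules), or ambient-temperature
magnitudes. Passing tests certify the machinery and the directional
physics, not quantitative property values of any real liquid.

**Observable fixtures.** Gaussian i.i.d. volumes with Var = κ_T·k_BT·⟨V⟩,
Gaussian dipole components sized to a requested ε_r(0), mean-volume
triplets at T±5 K encoding a requested α_P. These make the estimators
testable against their generating parameters with known √(2/n) sampling
error.

**Feature datasets.** 92 molecules; m_w uniform on 4–16 g/mol (average
atomic mass = molar mass / atom count — the chosen definition of m_w, with
molar mass trivially substitutable upstream), n_H uniform on
0.01–0.07 Å⁻³, α_P = 1.9×10⁻³ − 0.008·n_H + U(±0.5×10⁻³) K⁻¹ (weak
negative n_H coupling, sample correlation ≈ −0.4). The latent reduced
temperature g(m_w, n_H) = [8 + 55(1−e^{−n_H/0.03})]·[0.35 + 0.65·
e^{−((m_w−7)/4)²}] K is saturating-increasing in n_H and bump-shaped
(non-monotone) in m_w, spanning ≈5–45 K; Δ_vm = (g + N(0, 1.5 K))·α_P +
N(0, 0.0015). The noise scales are calibrated to mimic 4-replica SEMs:
large enough that the flat 3-feature forest measurably overfits the α_P
axis, small enough that the composite model's LOO R² stays ≈0.94.

## Machine-learning stage

Random forests use 20 trees, min_samples_split = 2, other hyperparameters
at scikit-learn defaults, seeds explicit everywhere. Leave-one-out
evaluation retrains per held-out molecule and repeats over 5 forest seeds,
reporting mean ± SEM of R²; tables under 10 rows are refused. Out-of-sample
R² may be negative (worse than the mean predictor) — the permutation-null
test requires exactly that. Shapley attribution treats the composite
f(m_w, n_H, α_P) = T̂(m_w, n_H)·α_P as one function of three inputs and
enumerates all 2³ coalitions with a marginal-expectation value function
over the supplied background table, so the efficiency identity holds to
machine precision; a Monte-Carlo permutation estimator is included purely
as a cross-check. Yeo–Johnson transforms (display normalization) delegate
to scipy, with λ fitted by maximum likelihood when unspecified. The n_H
grouping is 1-D k-means (k = 4, labels re-ordered by center so the
partition is input-order-independent) with a linear-kernel C-SVC (C = 1.0)
fit in (α_P, Δ_vm) for display margins.

## Interaction analyses

Profiles discretize the molecule-pair center-of-mass distance into 50 bins
on [3.3, 9] Å; pairs outside the window are dropped. Hydrogen bonds use
d(D···A) ≤ 3.6 Å and the D–H···A angle **at the hydrogen** ≥ 150°, both
boundaries closed; donors are O/N/S with a bound H, acceptors O/N (both
element sets configurable). Pair energies are the summed LJ + bare-Coulomb
terms between two molecules (no tail, configurable cutoff). Orientation
profiles require a bond selector matching exactly one bond per molecule
(e.g. the C–O bond of an alcohol) and report the mean inter-molecular
cosine. SEMs are the scatter across independent replicas.

## Numerical choices and degenerate inputs

- NVE conservation is asserted on half-window means of the extended
  Hamiltonian (the symplectic splitting leaves a bounded (ωΔt)²
  oscillation; the secular drift is < 10⁻⁵ over 10³ steps at 0.5 fs).
- QHO validation runs couple the PILE centroid at γ₀ = ω (critical
  coupling); with the liquid default 1 ps⁻¹ a tethered centroid
  decorrelates only every ~2 ps, far too slow for minute-scale budgets.
- SEMs of serially correlated series use block averages (20 blocks).
- Ratio statistics (Δ_λ, isotope effects) propagate SEMs by the
  first-order delta method; internal representation is a fraction,
  formatting renders percent.
- Degenerate inputs fail loudly: zero denominators in ratios, single-frame
  variances, missing temperature legs, empty Shapley backgrounds,
  non-finite forces (with the offending configuration), boxes below twice
  the cutoff, overpacked boxes.
- Energy minimization (L-BFGS on the classical coordinates) precedes the
  dynamics legs of liquid protocols to remove packing overlaps.

## Known limitations

Real-space electrostatics only; cubic boxes; no instantaneous pressure
observable (the barostat does not need the virial, and no tail-virial is
therefore exposed); no transport properties or finite-size dielectric
corrections; dielectric from fixed point charges only; the 1-4 exclusion
convention of the reference force field is unknown and left configurable;
desk-scale system sizes mean κ_T and ε_r(0) from the toy liquids carry
appreciable finite-size effects and are validated against synthetic
fixtures rather than against real-liquid values.
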