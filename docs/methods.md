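# Methods

Models, parameter choices, numerical decisions and known limitations of
each analysis stage.

## Ensemble reduction

A receptor ensemble (e.g. the models of an NMR structure) is compared
on a user-selected set of binding-site atoms. Pairwise RMSD is computed
after optimal rigid superposition of the site atoms using the Kabsch
algorithm (via quaternion/SVD least squares); the representative is the
**medoid**, the member minimising the sum of RMSDs to all others. Ties
are broken by the lower index so selection is deterministic. The CLI
reports site RMSDs in nanometres, the customary unit for NMR-ensemble
comparisons; the library API works in ångströms throughout.

## Empirical pose rescoring

The scoring function follows the AutoDock 4.0 semi-empirical free
energy model. For a ligand pose against a rigid receptor conformation:

- **Dispersion/repulsion**: pairwise 12-6 potential with
  Lorentz–Berthelot-style combination of per-type `Rii`, `epsii`.
- **Hydrogen bonding**: 12-10 potential between donor hydrogens (HD)
  and acceptors (OA, NA, SA), with well parameters `Rij_hb`,
  `epsij_hb`; coefficients `C = 5 ε r0¹²`, `D = 6 ε r0¹⁰`.
- **Electrostatics**: screened Coulomb term `q_i q_j / (ε(r) r)` with
  the Mehler–Solmajer sigmoidal distance-dependent dielectric
  (`A = −8.5525`, `λ = 0.003627`, `k = 7.7839`, `ε0 = 78.4`), energy
  conversion constant 332.0636 kcal·Å/(mol·e²). A constant dielectric
  can be substituted, in which case the term reduces exactly to
  Coulomb's law (verified to 10⁻⁹ in the tests).
- **Desolvation**: pairwise Gaussian volume term with σ = 3.5 Å and
  per-type atomic solvation parameters and volumes.
- **Torsional penalty**: `W_tor · N_rot`, proportional to the number of
  rotatable bonds.

Term weights are the published AutoDock 4.0 calibration
(vdW 0.1560, H-bond 0.0974, electrostatic 0.1465, desolvation 0.1159,
torsional 0.2744 kcal/mol). Pair interactions beyond a 20.48 Å cutoff
contribute exactly zero — the extent of AutoDock's interaction tables
(2048 bins × 0.01 Å); passing `nonbonded_cutoff=None` disables the
cutoff. A small atom-type parameter table covering the common organic
types ships with the package; alternative tables can be supplied as
TSV.

Poses with docked energy above −5 kcal/mol (configurable) are discarded
before clustering.

## Pose clustering and cluster selection

Pairwise pose RMSD (in-place, no re-superposition, matching docking
convention) feeds average-linkage agglomerative clustering (scipy). For
each candidate number of clusters `k` the dendrogram is cut and two
quality metrics are computed:

- **Davies–Bouldin index (DBI)** with medoid cluster centres: scatter
  is each cluster's mean distance to its medoid, and the index averages
  the worst-case ratio `(s_i + s_j)/d(medoid_i, medoid_j)`. Lower is
  better.
- **Explained pose variance**, `100·(1 − SSR/SST)` where SSR is the
  within-cluster sum of squared distances to the medoid and SST the
  same for the pooled data. Higher is better; non-decreasing in nested
  refinements.

The selected `k` is the first DBI local minimum whose explained
variance has plateaued (the next cut gains < 5 percentage points) and
that is *acceptable*: DBI ≤ 1.0, explained variance ≥ 90 %, and no
cluster smaller than two poses. Cuts containing singleton clusters are
excluded from candidacy altogether, because a singleton has zero medoid
scatter and makes the DBI degenerate (this is what lets a genuinely
unimodal pose cloud resolve to the trivial single cluster rather than
shattering). If no local minimum qualifies, the acceptable cut with
the lowest DBI is used; if none is acceptable, the pose set is treated
as one cluster.

A ligand/receptor combination passes the **consistency gate** when its
most populated cluster contains ≥ 25 % of the poses (inclusive). The
representative cluster is the most populated one among those passing
the gate, ties broken by lower minimum energy, then by cluster id; its
energy minimum is the ligand's preliminary binding energy.

## Ranking

Per ligand, the best (lowest) representative energy across all receptor
conformations that passed the gate defines the preliminary rank
(stable sort; dense ranks). Top hits are re-ranked by MM-PBSA binding
free energy. A published 14-compound rescoring table (docked rank,
docked energy, MM-PBSA binding energy) is packaged as data; sorting it
by MM-PBSA energy moves the compound docked at rank 185 to the top.
Rank agreement between the two orderings is reported as Spearman's ρ.

## MM-PBSA

Single-trajectory formulation: complex, receptor and ligand energies
are evaluated on the same snapshots and averaged,
`ΔG = ΔE_MM + ΔG_polar + ΔG_nonpolar − TΔS`.

- **Molecular mechanics**: harmonic bonds `k(r−r0)²` and angles,
  AMBER-style torsions `v_n/2·(1+cos(nφ−γ))`, 12-6 Lennard-Jones with
  Lorentz–Berthelot mixing, Coulomb electrostatics at interior
  dielectric 1, with 1-2 and 1-3 exclusions.
- **Polar solvation**: finite-difference Poisson solver (zero ionic
  strength). Red-black successive over-relaxation on a uniform grid;
  dielectric defined on grid edges with harmonic-mean averaging across
  the solute boundary (fractional-edge treatment); boundary potentials
  from the Coulomb/ε_out far field; grid self-energy removed by
  solving the same system with ε ≡ ε_in and subtracting, which cancels
  the discretisation self-energy exactly in the Born limit. Complex,
  receptor and ligand are solved in the **same grid box** so grid
  artefacts cancel in the difference. Convergence to 10⁻⁶ relative
  residual, with a hard iteration cap that raises rather than returning
  unconverged numbers. Verified against the Born ion (< 2 % at 0.25 Å
  spacing, converging monotonically with refinement) and a Kirkwood
  two-charge spherical cavity (< 5 %).
- **Nonpolar solvation**: `γ·SASA + β` with γ = 0.00542 kcal/(mol·Å²),
  β = 0.92 kcal/mol. SASA by Shrake–Rupley with 960 golden-spiral
  points per atom and a 1.4 Å probe (single-atom case exact to 10⁻¹²).
- **Entropy** (optional): normal-mode analysis at each snapshot —
  finite-difference Hessian, mass-weighting, projection of the six
  rigid-body modes, harmonic-oscillator vibrational entropy plus
  Sackur–Tetrode translational and rigid-rotor rotational terms at
  300 K. Requires the geometry to be at a minimum (checked; a steepest
  descent pre-minimisation is applied by default).

## Fluorescence quenching

The titration records intrinsic fluorescence intensity versus ligand
concentration. An optional inner-filter correction rescales intensities
by the ratio of a ligand-only control to its zero-ligand value. The
binding fit uses the double-reciprocal linearisation

    1/ΔFI = 1/ΔFI_max + 1/(K_A · ΔFI_max · [L]),

with `ΔFI = FI_0 − FI`. The association constant is the fitted
intercept/slope ratio, `K_d = 1/K_A`, and the bimolecular quenching
rate `K_Q = K_A/τ0` with the fluorophore lifetime τ0 = 10 ns.
`K_Q > 2×10¹⁰ M⁻¹s⁻¹` (the diffusion-collision ceiling) is classified
as static quenching; values at or below it are reported as within the
dynamic-scatter limit. A weighted nonlinear fit and a residual
bootstrap for the `K_A` uncertainty are provided as cross-checks; the
double-reciprocal form remains the primary estimator because it is the
standard analysis for these titrations, despite its known tendency to
overweight the low-concentration points.

## Cytotoxicity and synergy

Viability is converted to affected fraction `fa = 1 − v` and fit with
the median-effect line `log10(fa/(1−fa)) = m·log10(D) − m·log10(Dm)` by
ordinary least squares; points with `fa ∈ {0, 1}` or zero dose are
excluded with a warning (the transform is undefined there). IC50 is
`Dm` by definition, with a model-free log-linear interpolation of the
0.5 crossing as an alternative. For a fixed-ratio combination the
combination index at effect level `x` is
`CI = d_a/D_x,a + d_b/D_x,b` (mutually exclusive form), where `d` are
the doses of each agent in the mixture achieving `fa = x` and `D_x` the
single-agent doses; CI < 0.9 synergy, 0.9–1.1 additivity, > 1.1
antagonism. A drug combined with itself yields CI = 1 identically, a
property the tests enforce to 10⁻⁶.

## Synthetic data generators

All generators take an integer seed and are fully deterministic.

- **Ensembles**: a common random site geometry perturbed per member by
  zero-mean displacements; one member gets a 4× smaller perturbation,
  planting a known medoid. The default spread puts pairwise site RMSDs
  in the 1–3 Å range typical of a relaxed NMR ensemble.
- **Pose clouds**: Gaussian clusters around well-separated centres with
  planted labels, per-cluster energy offsets (lower for the intended
  cluster) and optional exact population fractions, emitting real
  `Pose` objects so the fixtures exercise the production code path.
- **Toy complexes**: two short chains (receptor and ligand) with bonds,
  angles, torsions, charges and LJ parameters, optionally
  non-interacting (ligand charges and LJ zeroed) so binding terms
  vanish identically — used as an MM-PBSA null oracle. A Born ion
  builder provides the PB analytic benchmark.
- **Titrations**: the saturable binding isotherm on a 0–320 µM ligand
  grid with multiplicative noise on ΔFI and an optional synthetic
  inner-filter attenuation.
- **Dose–response**: exact median-effect curves on a geometric dose
  grid spanning Dm/8–8·Dm plus a zero-dose point, with additive
  viability noise clipped to [0, 1]; an equal-slope additive-mixture
  builder generates combinations with CI = 1 ground truth.

## Numerical choices

Float64 throughout; stable sorts everywhere ranks are assigned; all
stochastic code draws from `numpy.random.default_rng` seeded
explicitly; pipeline CSV/JSON output uses fixed float formatting and
sorted keys so reruns are byte-identical. The Poisson solver optionally
uses numba JIT when available, falling back to vectorised numpy.

## Limitations

- The absolute MM-PBSA energies of the packaged published table cannot
  be recomputed here: doing so would require the original structures,
  force-field assignment and trajectories. The package reproduces the
  *re-ranking* analysis, and its own MM-PBSA implementation is
  validated against analytic oracles (Born, Kirkwood, closed-form
  entropies) on toy complexes instead.
- The PB solver is a zero-salt Poisson solver (no Boltzmann ion term)
  on a uniform grid; accuracy is grid-limited (≈ 0.1–2 % for ions at
  0.25–0.5 Å) and cost grows as the cube of the box size.
- Single-trajectory MM-PBSA neglects conformational relaxation of the
  unbound species, and normal-mode entropy assumes a harmonic well.
- The double-reciprocal binding fit is exact on noise-free data but
  amplifies noise at low ligand concentration; over 200 replicates at
  2 % intensity noise the median K_A error is ≈ 3–4 %.
- Median-effect regression after the log-odds transform is unbiased
  (ensemble mean within 0.5 % at 1 % viability noise) but individual
  replicates at extreme effect levels can deviate by a few per cent;
  confidence in Dm should come from replicate ensembles.
- The empirical scoring function implements the standard pairwise
  terms with a simplified angular treatment of hydrogen bonding (the
  full AutoDock directionality ramp is available as a helper but the
  pair scorer treats H-bonds isotropically, as docking-log rescoring
  lacks the bonding topology needed for lone-pair geometry).
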