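# Methods

This note records the models implemented in trajlens, the defaults chosen
where the underlying methodology leaves choices open, and what the
synthetic benchmarks do and do not demonstrate about real data.

## Units and conventions

Coordinates in Å, time in ns, masses in amu, charges in elementary units,
energies in kcal/mol.  Atom indices are 0-based internally; residue ids are
kept 1-based exactly as read from the input file and all reports use
residue ids.  Multi-model PDB (MODEL/ENDMDL) is the canonical trajectory
dialect, XYZ a secondary one; binary formats are out of scope.  Per-atom
energy parameters (charge, Rmin/2, ε, intrinsic Born radius, HCT screening
factor) are supplied as a plain table rather than parsed from a force
field: the energetics need only per-atom constants, and force-field
preparation is upstream of this package.

The selection grammar is deliberately small: `backbone` (atoms named N,
CA, C, O), `resid A-B`, `chain X`, `all`, with `and` for intersection and
`or` for union (`or` added because partitions like "both DNA strands" are
naturally a union of chains).  Selections are deterministic and sorted.

## Superposition, RMSD, RMSF

Weighted Kabsch superposition via SVD of the weighted cross-covariance,
with the reflection guard on the smallest singular value.  The same code
path runs batched (stacked 3×3 SVDs) for per-frame series and for the
all-pairs matrix.  Two numerical details matter:

- For single fits and frame series the RMSD is evaluated from the
  explicitly rotated coordinates; the alternative trace formula loses half
  the machine digits near zero (identical structures come out at ~1e-7
  instead of ~1e-14).
- The all-pairs matrix does use the trace formula for speed, with a
  relative clamp (`msd < 1e-12·scale → 0`) that removes exactly that
  rounding artefact; at the matrix's resolution this is inconsequential.

Mass weighting is on by default everywhere and can be disabled.  RMSD
supports distinct fit and report selections (fit on backbone, report on a
loop is how the FMA functional quantity is built).

RMSF is the root time-mean squared deviation from the time-mean position,
averaged into residues with mass weights.  The alignment target is
configurable: iterated mean structure (default; matches the sqrt(3)·σ
closed form used in validation), first frame, or none (for trajectories
already in a common frame, e.g. mode-filtered ones).  Note that
superposition itself absorbs 6 of the 3N fluctuation degrees of freedom,
biasing RMSF low by a factor ≈ sqrt(1 − 2/N); validation uses chains large
enough (N = 200 atoms) that this bias is well inside the 2% test band.

The equilibration detector compares sliding-window means against the
final-window mean and returns the first index from which all subsequent
window means stay within tolerance; a plateau shorter than one extra full
window does not count, so monotonically drifting series report
"never settled" (last frame, with a warning).  Defaults: window = 5% of
the series, tolerance 0.3 Å — stated defaults, not tuned quantities, since
the plateau rule itself has no canonical parameterisation.

## PCA and functional mode analysis

PCA diagonalises the covariance of mass-weighted, rigid-aligned
fluctuations q = sqrt(m)(x − ⟨x⟩); eigenvalues are in Å²·amu.  The FMA
regression is ordinary least squares (with intercept) of the scalar
functional quantity on the projections of the leading modes; for a linear
model, maximising the Pearson correlation and least squares coincide.
Reported vectors: MCM ∝ Σβ_k e_k and ewMCM ∝ Σβ_k λ_k e_k, both unit in
the weighted coordinate space; `mode_to_cartesian` back-transforms for
comparison with Cartesian displacement fields.

Open choices and their defaults:

- Retained modes: smallest count explaining 90% of variance (overridable).
- Cross-validation split: first half train / second half validate
  (overridable fraction).  r_train and r_cv are both reported; r_cv is the
  honest number.
- The functional quantity is the RMSD of a sub-selection after fitting the
  full selection.  When that RMSD is taken against a reference the
  trajectory fluctuates around, the map from mode amplitude to RMSD folds
  at zero (RMSD is non-negative) and the linear model degrades; the
  pipeline therefore accepts an explicit reference structure for the
  functional series, and the planted-mode generator offsets the amplitude
  mean so the planted relation stays one-signed.

Mode filtering reconstructs frames as mean + projection·mode, removing all
orthogonal variance; the RMSF of the filtered trajectory (computed without
re-alignment — the frames are already in the model's frame) identifies the
residues carrying the correlated motion.  A caveat discovered while
validating: a displacement field localised on a residue range is generally
*not* orthogonal to the rigid-body subspace, and superposition silently
removes its rigid component.  The generator therefore projects planted
modes onto the rigid-free subspace (mass-weighted), which spreads a small
compensating displacement over the remaining atoms; strictly-zero RMSF
outside the planted region holds only in the no-alignment setting.

## Clustering

The pairwise matrix holds superposition-minimised mass-weighted RMSD
between strided frames (each pair fitted independently, so the triangle
inequality is not guaranteed).  Merging is agglomerative via
scipy.cluster.hierarchy (average linkage default; complete, centroid and
single available), cut at every candidate K; labels are renumbered by
first appearance so results are deterministic.

The quality metrics require a variance decomposition (SST = SSR + SSE),
which is only exact in a fixed coordinate frame; they are therefore
computed after a single common superposition of all frames to their mean,
in coordinates scaled by sqrt(m_a/M) so Euclidean distance equals
mass-weighted RMSD.  Definitions: SST = Σ‖x_f − x̄‖², SSE the
within-cluster analogue, pSF = (SSR/(K−1))/(SSE/(F−K)), DBI the mean over
clusters of max_j (S_i + S_j)/M_ij with S_i the mean member distance to
the cluster mean and M_ij the distance between cluster means.  These
coincide with the standard Calinski-Harabasz and Davies-Bouldin scores and
are cross-checked against scikit-learn and against a brute-force
implementation in the tests.

Cluster-count rule: K must sit at a local DBI minimum *and* show a
relative SSR/SST gain to K+1 below `plateau_tol` (default 0.05); among
candidates the largest pSF wins; if no K qualifies, the DBI arg-min is
returned with a warning.  Centroids are medoids in the pairwise-RMSD
sense; populations are member fractions.  The default stride targets
roughly 1200 strided frames, a size at which the full matrix (≈7·10⁵
pairs) takes a few seconds.

## MM/GBSA

Single-trajectory thermodynamic cycle: ΔΔG = G(complex) − G(receptor) −
G(ligand) with all three species taken from the same complex frame.
Consequences exploited (and asserted, not recomputed): internal bonded
terms cancel identically, so `e_internal` is exactly 0; gas-phase
electrostatic and van der Waals differences reduce to the receptor-ligand
cross interaction.  The entropy term is held constant across compared
systems and is never reported.

Term by term:

- Coulomb: k q_i q_j / (ε_in r), k = 332.0636 kcal·Å/(mol·e²).
- Lennard-Jones 12-6 in the Rmin/2 convention with Lorentz-Berthelot
  combination; pair minimum exactly −ε_ij at r = rmin_ij.
- Born radii: HCT pairwise descreening, 1/α_i = 1/ρ_i − Σ_j H(r, ρ_i,
  s_j ρ_j), with the closed-form Coulomb-field integral H including the
  partial-overlap (L = ρ_i) and engulfed (L = s_jρ_j − r, plus the full
  inner-shell term) branches.  The implementation was verified against
  numerical quadrature of the descreening integral to ~1e-10 in all three
  branches.  No dielectric offset is subtracted from the intrinsic radii,
  so an isolated atom's effective radius equals its intrinsic radius
  exactly.  The inverse radius is floored at a small positive value as a
  guard for pathologically overlapped geometries.
- GB energy: Still's f_GB = sqrt(r² + α_iα_j exp(−r²/4α_iα_j)) over the
  full double sum (cross pairs counted twice, self terms once), so a
  single ion reproduces the Born formula exactly.  ε_in = 1,
  ε_solv = 78.5, no salt screening; all configurable.
- SASA: Shrake-Rupley with a golden-spiral point set, probe 1.4 Å, 960
  points, γ = 0.005 kcal/mol/Å², β = 0.  Discretised SASA is not
  intrinsically rotation-invariant, so coordinates are first canonicalised
  to a principal-axes frame (signs fixed by third moments) — a
  deterministic function of the configuration — making the area exactly
  invariant under rigid motions of the input.  The complex and its two
  species are evaluated in the *same* canonical frame so the SASA
  difference vanishes identically at infinite separation.
- No pair cutoffs anywhere: systems at this scale afford exact all-pairs
  sums.

Per-residue decomposition assigns half of each cross pair term to each
partner atom's residue, GB rows of the symmetric pair matrix to the owning
atom, and per-atom SASA differences to the owning atom (a non-zero β is
spread uniformly); the residue table therefore sums to the total exactly,
which the tests assert per frame at 1e-6 kcal/mol.  The conventional
reporting filter |mean| > 1 kcal/mol is available as
`ResidueDecomposition.significant()`.

The mean ± SD over frames uses the population standard deviation.

A limit worth knowing: "every ΔΔ term vanishes at large separation" holds
at the 1e-6 kcal/mol level only for species without net monopole/dipole —
the bare Coulomb tail of a ±1e pair at 500 Å is still 0.66 kcal/mol.  The
separability benchmark therefore uses an apolar ligand (exercising the
vdW, GB-descreening and SASA channels at 1e-6), and charged-pair
electrostatics are checked separately for monotone 1/r decay.

## Synthetic data: what it does and does not show

The generators produce: (a) isotropic Gaussian fluctuation about a
procedurally built poly-alanine-like backbone (4 atoms/residue on a gentle
helix) with one planted collective mode of known per-frame amplitude;
(b) multi-state ensembles drawn from displaced copies of the chain with
stated occupancies — the default benchmark uses occupancies
(0.55, 0.36, 0.06, 0.03) over 1200 frames, a two-dominant-cluster
structure typical of equilibrated Boltzmann sampling, with between-state
separation 10× the within-state width; (c) toy complexes (two oppositely
charged ions; two short neutral chains with alternating partial charges;
random-packed atoms) with physically reasonable radii and ε.

These fixtures validate the *estimators*: that superposition finds the
global rotational minimum, that FMA recovers a planted mode at SNR 10 with
cross-validated r ≥ 0.9, that the cluster-count rule finds a planted K = 4
in ≥ 95% of seeds, that the energy terms match their closed forms.  They
do not emulate anharmonicity, solvent memory, fat-tailed displacement
distributions, force-field realism, or conformational exchange on the
trajectory's own timescale — so passing them says the machinery is
correct, not that any particular biological conclusion transfers.
Absolute binding energies of real protein-DNA systems additionally depend
on the force-field parameters supplied, which this package deliberately
takes as input.

## Problem sizes used in validation

Chosen to make every check definitive on one CPU in minutes: RMSF closed
form at 50,000 frames × 200 atoms; FMA recovery over 20 seeds at 2,000
frames (null model at 10,000); clustering at 1,200 frames × 40 atoms over
20 seeds; brute-force metric oracles at ≤ 12 frames (exact arithmetic);
MM/GBSA toys at ≤ 32 atoms where all-pairs sums and quadrature oracles are
exact.

## Known limitations

- No periodic-boundary re-imaging or solvent stripping; trajectories are
  assumed pre-processed.
- Centroid linkage on a non-Euclidean RMSD matrix can produce inversions
  (inherited from the method, not the implementation); average linkage is
  the default.
- The HCT radii floor (inverse radius ≥ 1e-8 Å⁻¹) is a guard, not a
  physical model, for geometries far more overlapped than any sensible
  input.
- The pipeline's RMSD-based functional quantity folds when the reference
  sits inside the sampled ensemble (see the FMA section); supply an
  external reference when the functional region fluctuates symmetrically.
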