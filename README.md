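# trajlens

Conformational analysis of molecular-dynamics trajectories and
single-trajectory MM/GBSA binding energetics, in plain scientific Python.

The package implements the analysis workflow used to characterise how a
point mutation changes the dynamics of a DNA-binding protein (the
motivating system is the p53 DNA-binding domain and its G245S hotspot
mutant): equilibration-aware RMSD/RMSF profiles, functional mode analysis
to find the collective motion coupled to a flexible loop, RMSD-based
hierarchical clustering with quantitative cluster-count selection, and
generalized-Born/surface-area binding free energies with per-residue
decomposition.  Because μs-scale production trajectories are rarely
deposited, the package ships first-class synthetic-data generators with
planted, exactly known ground truth, so every stage is testable end to end
on a desk machine.

## What it computes

**Superposition, RMSD, RMSF.**  Mass-weighted Kabsch superposition
(batched over frames or frame pairs); per-frame RMSD after fitting one
selection and reporting on another (fit on backbone, report on backbone by
default); per-residue RMSF about the time-mean structure,

&nbsp;&nbsp;&nbsp;&nbsp;RMSF_i = sqrt( ⟨ |x_i(t) − ⟨x_i⟩|² ⟩_t ),

plus a sliding-window plateau detector for the equilibrated window.

**Functional mode analysis (FMA).**  With PCA modes e_k (eigenvalues λ_k)
of the mass-weighted positional covariance and a scalar functional
quantity f(t) — here the RMSD of a loop region — ordinary least squares of
f on the mode projections p_k(t) gives coefficients β_k.  The maximally
correlated motion is MCM ∝ Σ β_k e_k and its ensemble-weighted variant
ewMCM ∝ Σ β_k λ_k e_k (both unit-normalised); maximising the Pearson
correlation of a linear model and least squares coincide.  The correlation
is reported on the training split (r_train) and a held-out split (r_cv),
and the trajectory can be filtered onto the ewMCM to read off, via RMSF,
which residues carry the correlated motion.

**Clustering.**  All-pairs mass-weighted RMSD between (strided) frames;
agglomerative merging (average, complete, centroid linkage); quality
metrics over a candidate count range K — Davies-Bouldin index (DBI),
pseudo-F statistic (pSF = (SSR/(K−1))/(SSE/(F−K))), and the explained
variance ratio SSR/SST.  The chosen K sits at a local DBI minimum where
the SSR/SST curve has plateaued, ties broken by the largest pSF.  Cluster
centroids are medoids (smallest summed RMSD to the other members) and
populations are frame fractions.

**MM/GBSA.**  Single-trajectory binding energy between a receptor and a
ligand partition of a complex,

&nbsp;&nbsp;&nbsp;&nbsp;ΔG_bind ≈ ΔE_elec + ΔE_vdW + ΔG_GB + ΔG_SA,

with receptor/ligand coordinates extracted from the same complex frame so
internal bonded terms cancel identically.  Electrostatics are Coulomb
(k = 332.0636 kcal·Å/mol·e²), dispersion is 12-6 Lennard-Jones
(Lorentz-Berthelot, Rmin/2 convention), polar solvation is generalized
Born with Hawkins-Cramer-Truhlar pairwise-descreening effective radii and
Still's f_GB, and the nonpolar term is γ·SASA (Shrake-Rupley).  The
entropy change −TΔS is treated as constant across compared systems and
never reported.  Per-residue decomposition splits every pairwise term half
to each partner and conserves the total exactly.

**Synthetic data.**  Gaussian ensembles with a planted collective mode
(known amplitudes), multi-state ensembles with stated occupancies (known
labels), and toy receptor-ligand complexes (two-ion, helix-pair,
random-packed) whose energies have closed forms.

## Worked example

```python
import numpy as np
import trajlens as tl

# 30-residue backbone chain with a planted collective mode on the "loop"
# residues 10-16, sampled for 2000 frames at SNR 10
chain = tl.build_chain(30)
mode = tl.make_localized_mode(chain, 10, 16, seed=0)
spec = tl.PlantedModeSpec(mode=mode, amplitude_sd=1.0, amplitude_mean=4.0,
                          noise_sd=0.1, n_frames=2000, seed=0)
traj, amplitudes = tl.generate_planted_mode_trajectory(chain, spec)

sel = tl.make_selection(chain, "all")
loop = tl.make_selection(chain, "resid 10-16")

profile = tl.rmsf_per_residue(traj, sel)
print(f"RMSF peak at residue {profile.residue_ids[np.argmax(profile.values)]}: "
      f"{profile.values.max():.2f} A")

model = tl.fit_pca(traj, sel)
f = tl.functional_rmsd(traj, loop, chain, sel)
n = model.n_components_for_variance(0.9)
proj = tl.project(traj, model, np.arange(n))
res = tl.fit_fma(model, proj, f, n_components=n)
cos = abs(np.sum(tl.mode_to_cartesian(model, res.ewmcm) * mode))
print(f"FMA: r_train={res.r_train:.3f}, r_cv={res.r_cv:.3f}, "
      f"cosine(ewMCM, planted)={cos:.3f}")

states = tl.make_states(chain, 4, separation=3.0, seed=0)
ms = tl.MultiStateSpec(states=states, occupancies=[0.55, 0.36, 0.06, 0.03],
                       within_state_sd=0.3, n_frames=1200, seed=0)
mtraj, _ = tl.generate_multistate_trajectory(ms)
cres = tl.cluster_trajectory(mtraj, sel)
pops = ", ".join(f"{100*p:.0f}%" for p in cres.populations)
print(f"clustering: chosen K={cres.chosen_k}, populations {pops}")

topo, params, ctraj = tl.generate_toy_complex(
    tl.ToyComplexSpec(geometry="two-ion", separation=5.0, n_frames=5, seed=0))
rec = tl.make_selection(topo, "chain A")
lig = tl.make_selection(topo, "chain B")
be = tl.trajectory_binding_energy(ctraj, rec, lig, params)
m = be.term_means()
print(f"two-ion BE = {be.mean:.2f} +/- {be.sd:.2f} kcal/mol "
      f"(elec {m['e_elec']:.2f}, vdW {m['e_vdw']:.2f}, "
      f"GB {m['g_gb']:.2f}, SA {m['g_sa']:.2f})")
```

prints

```
RMSF peak at residue 13: 0.28 A
FMA: r_train=0.999, r_cv=0.999, cosine(ewMCM, planted)=0.999
clustering: chosen K=4, populations 52%, 39%, 6%, 3%
two-ion BE = -0.86 +/- 0.01 kcal/mol (elec -66.51, vdW -0.03, GB 65.78, SA -0.09)
```

Reading the output: the RMSF peak lands inside the planted loop; FMA
recovers the planted collective mode essentially perfectly (cosine 0.999)
with a cross-validated correlation of 0.999; the cluster-count rule picks
K = 4 and the recovered populations track the planted 55/36/6/3%
occupancies to within sampling error; and for a ±1e ion pair in implicit
water the generalized-Born desolvation penalty (+65.8) almost cancels the
bare Coulomb attraction (−66.5), leaving a net binding energy of
−0.9 kcal/mol — the physically expected near-cancellation in a
high-dielectric solvent.

## Command line

```bash
trajlens simulate planted-mode --residues 20 --frames 300 --seed 4 --out pm/
trajlens rmsf --traj pm/trajectory.pdb --select backbone --out rmsf.csv
trajlens cluster --traj ms/trajectory.pdb --select all --kmax 8 --out clusters/
trajlens mmgbsa --traj tc/complex.pdb --params tc/complex.params \
    --receptor "chain A" --ligand "chain B" --out be/
trajlens run --config analysis.yaml     # full pipeline from one config
trajlens compare runA/ runB/            # paired wt-vs-mutant difference tables
```

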