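# gpcrdyn

Intrinsic-dynamics analysis of membrane receptors: does the large
conformational change seen in a trajectory of a 7-helix (GPCR-like)
receptor — the third intracellular loop (ICL3) packing under the receptor
core, dragging the lower end of TM6 with it — follow from the receptor's
*intrinsic* mechanics, or is it an accident of the simulation? The package
answers this the standard way: compare the essential (PCA) modes of the
trajectory with the normal modes of a coarse-grained elastic network of the
same structure embedded in a membrane, and quantify the transition itself
with region-fitted RMSD profiles, windowed RMSF, center-of-mass offsets and
RMSD-cutoff clustering.

It is aimed at structural-bioinformatics users who have C-alpha level
structures/trajectories (multi-model PDB) and want the full pipeline —
typed protein+membrane anisotropic network model (ANM), essential-dynamics
PCA, subspace overlap, trajectory metrics, snapshot clustering — with every
stage testable against synthetic data with planted ground truth.

## The models

**Membrane-embedded ANM.** Nodes are protein C-alphas plus membrane spheres
on an FCC lattice (slab of 80 Å diameter × 33 Å thickness, 8 Å
nearest-neighbor spacing, clipped to a cylinder). Node pairs within a
cutoff r_c = 11 Å are connected by harmonic springs with force constants by
contact type: γ_pp = 1.0 (protein–protein), γ_pm = 2.0 (protein–membrane),
γ_mm = 4.0 (membrane–membrane). The Hessian super-element for a connected
pair is

    H_ij = −(γ_ij / r_ij²) (r_ij ⊗ r_ij),   H_ii = −Σ_{j≠i} H_ij ,

whose eigenvectors **u**_j (after removing the six rigid-body zero modes of
a connected network) are the intrinsic modes, slowest first. The membrane
constrains the transmembrane helices so that they do not fluctuate
unrealistically as they would in a protein-only network.

**Essential dynamics.** Frames are superposed onto the initial structure
(Kabsch, proper rotations only), and the covariance of the centered
C-alpha coordinates is diagonalized. Eigenvectors **p**_i (descending
eigenvalue λ_i) are the essential modes; λ_i/Σλ is the fraction of total
motion that mode explains; projecting frames on a subset of modes
reconstructs a reduced trajectory.

**Subspace overlap.** Agreement between the two mode sets is the average
overlap (RMSIP) over the first k = 10 modes,

    O_ave = sqrt( (1/k) Σ_{i≤k} Σ_{j≤k} (**p**_i · **u**_j)² ),

which is 1 exactly when the two k-subspaces coincide, plus single-mode
overlaps O_ij = |**p**_i · **u**_j| and region-restricted variants (both
vector sets truncated to a region's components and renormalized).

**Transition metrics and clustering.** Region-fitted RMSD (fit region and
measured region may differ — e.g. loop RMSD after core alignment), RMSF per
residue about a time window's average structure, atom-pair distance and
side-chain dihedral profiles, ionic-lock style minimum polar-atom
distances, center-of-mass axis offsets, and greedy most-neighbors RMSD
clustering at a fixed cutoff.

Because trajectories of this kind are rarely deposited, the package ships a
first-class synthetic-data generator: an idealized 7-helix bundle
(330 residues, flexible loop at 231–262, lower TM6 at 267–282) and
trajectories built from planted orthonormal modes with prescribed
variances, a planted two-state mean shift, isotropic noise and per-frame
rigid-body jitter — so every stage is validated against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole workflow on the
synthetic demo (a 1000-frame, 200 ns-equivalent trajectory whose
fluctuations follow the ten slowest protein-restricted ANM modes and whose
loop packs against the core at 70% of the run):

```
$ python analysis/01_build_system.py --seed 1
bundle: 330 CA atoms, ...
network: 680 nodes (350 membrane), cutoff 11.0 A, connected: True
rigid-body modes removed: 6
slowest eigenvalues: [0.00027 0.00028 0.0003  0.00164 0.00178]

$ python analysis/03_essential_dynamics.py --seed 1
variance fractions: mode1 47.3%, top5 [47.3  3.8  3.3  3.   0.7]%
TM6-lower RMSD step across the transition (original): 1.01 A
TM6-lower RMSD step across the transition (mode1): 1.59 A
TM6-lower RMSD step across the transition (modes1-5): 1.58 A
mode-1 projection step: 62.1x the within-state spread

$ python analysis/04_mode_overlap.py --seed 1
average overlap (k=10): 0.878

$ python analysis/05_transition_and_clustering.py --seed 1
RMSD ICL3_fit_CORE: pre 0.74 A -> post 4.17 A
loop RMSF: full run 1.83 A, post-transition window 0.54 A
clustering (INTRA at 1.8 A, fit TMEMB): 2 clusters, occupancies [70. 30.]%,
state purity 100.0%
```

Reading the output: the first essential mode alone carries the planted
packing transition (the mode-1 projection steps by 62 standard deviations
at the planted frame, and the mode-1 reconstruction reproduces the TM6
displacement), the essential subspace agrees with the network's intrinsic
modes (O_ave = 0.88 at k = 10), the loop quiets down after packing (RMSF
1.83 → 0.54 Å), and clustering the intracellular region at a 1.8 Å cutoff
recovers the two planted states at their exact 70/30 occupancies.

The same workflow is available as a single call,
`gpcrdyn.pipeline.run_pipeline(RunConfig(...))`, which writes all profiles,
mode files, overlap matrices, cluster tables and a `summary.json` tagged
with the config hash.

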