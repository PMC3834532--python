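# Methods

This note records the models, the numerical choices, and the reasoning
behind the design decisions that were genuinely open.

## Elastic network model

The anisotropic network model treats each protein C-alpha and each
membrane sphere as a node; node pairs within a cutoff r_c interact through
a harmonic spring penalizing changes of the pair distance. The energy is
quadratic in displacements, with 3×3 Hessian super-elements
H_ij = −(γ_ij/r_ij²)(r_ij ⊗ r_ij) and diagonal blocks enforcing
translational invariance. Eigenvectors of the Hessian with the six
rigid-body zero modes removed are the intrinsic modes; low eigenvalues are
soft collective motions. Assumptions worth keeping in mind: single-parameter
harmonic springs (no sequence specificity), C-alpha resolution, and a
static reference geometry — the model describes fluctuations *about* the
input conformation, not barrier crossings.

Parameters (defaults):

| parameter | default | units | rationale |
|---|---|---|---|
| cutoff r_c | 11 | Å | standard C-alpha ANM interaction range for this system class |
| γ protein–protein | 1.0 | arb. | reference stiffness |
| γ protein–membrane | 2.0 | arb. | membrane couples more stiffly to the protein |
| γ membrane–membrane | 4.0 | arb. | membrane slab stiffer than protein |
| slab diameter | 80 | Å | covers the bundle footprint with margin |
| slab thickness | 33 | Å | hydrophobic thickness of a phosphatidylcholine bilayer |
| FCC nearest-neighbor spacing | 8 | Å | below r_c so lattice neighbors are always connected; density comparable to lipid headgroup packing. Not a literature constant — exposed as a parameter |
| clash radius | 4 | Å | membrane node removed if within this distance of any protein node; exposed as a parameter |

The slab footprint is a cylinder (a "diameter" implies a round patch, and a
cylinder keeps the boundary equidistant from the protein). Embedding
centers the transmembrane region's C-alpha centroid at the slab center and
aligns its principal axis with z; the optional tilt flag (default off)
rotates the protein by a fixed angle about x for users who want the
membrane-normal offset sometimes used when building bilayer systems.
Embedding refuses disconnected networks: a disconnected network has more
than six zero modes and every downstream mode index would silently shift.

Numerics: the Hessian is assembled dense (3N ≤ ~2500 here); eigenpairs come
from LAPACK subset solves (lowest n+6 plus the largest one). A mode counts
as rigid-body when λ < 1e-8·λ_max; more than six such modes raises a
disconnection error rather than silently dropping modes. Eigenvector sign
is fixed by making the largest-magnitude component positive, so outputs are
deterministic. Restricting modes to a node subset truncates components and
renormalizes; a mode with (near-)zero norm on the region is kept as a zero
vector and flagged, and overlap entries involving it are NaN.

## Essential dynamics

Frames are superposed with the Kabsch algorithm (proper rotations only —
reflections are never used, so mirror-image geometries keep a positive
RMSD). The alignment reference is the initial frame, per the usual
convention for transition detection; PCA centering uses the trajectory
mean. Both conventions are recorded in the result object because they
differ. The covariance of the aligned, centered C-alpha coordinates is
diagonalized through an SVD of the data matrix (numerically stabler than
forming the covariance). The full eigenvalue spectrum is kept alongside
the retained modes so variance fractions are always relative to the total
variance. The PCA fit region defaults to all protein C-alphas and is
configurable, as is a frame range for excluding an equilibration stage.
Mass weighting is deliberately absent: the analysis is C-alpha-level and
unweighted throughout (a flag on the center-of-mass offsets allows
mass-weighted centroids if ever needed — with identical pseudo-residues it
changes nothing).

Reconstruction from a mode subset K is frame_t = mean + Σ_{i∈K}
proj_i(t)·p_i; with K = all modes this reproduces the aligned trajectory to
machine precision, which the tests assert — it is the completeness check
for the whole PCA path.

## Average overlap

The average overlap between the leading k-subspaces is implemented as
RMSIP: the 1/k sits inside the square root, so identical subspaces score
exactly 1 and orthogonal ones 0. The alternative placement (1/k outside
the root) caps identical subspaces at 1/√k ≈ 0.32 at k = 10, which makes
reported values in the 0.6–0.9 range impossible to interpret as "close to
1"; it remains available behind a `literal=True` flag for comparison.
k defaults to 10, the conventional size of a collective subspace.

Comparing trajectory PCA (protein-only) with the mixed-network ANM forces
one extra step the analysis makes explicit: ANM modes are restricted to
the protein nodes and renormalized before any inner product. Whether to
renormalize after restriction is a genuine choice; renormalization is the
default because only then is the restricted overlap a cosine.

## Trajectory metrics

All RMSD-type metrics separate the *fit* region (superposition) from the
*measure* region, so e.g. loop displacement can be measured in the frame
of the rigid core. Distances and dihedrals are computed on raw coordinates
and are exactly invariant under per-frame rigid motion (asserted to 1e-9).
RMSF is computed about the time window's average structure after aligning
window frames on the fit region. Center-of-mass offsets use unweighted
C-alpha centroids and are only meaningful after aligning the trajectory to
a common frame (the analysis aligns on the core region to frame 0). The
ionic-lock metric takes the per-frame minimum over the
guanidinium-nitrogen × carboxylate-oxygen pairs, because the chemistry
names atom classes rather than a unique atom pair, and reports the
C-alpha–C-alpha distance alongside. Side-chain dihedrals take four
explicit atom names; for a glutamate "χ" both χ3 (CB–CG–CD–OE1, the
carboxylate rotation that can break a salt bridge) and any other definition
are expressible, since the atom quadruple is caller-supplied — the package
does not hard-code which χ is meant.

## Snapshot clustering

Greedy most-neighbors ("GROMOS-style") clustering: after a single
alignment pass onto frame 0 using the fit region, pairwise RMSDs over the
measure region are thresholded; the frame with the most neighbors becomes
a centroid, its neighborhood is removed, and the rule repeats. Ties go to
the lowest frame index, so results are deterministic. This algorithm was
chosen for determinism and ubiquity where the clustering rule is not
otherwise pinned down. A mutual pairwise-superposition variant exists for
small frame counts (the single-pass convention makes the n×n RMSD matrix
computable by one Gram product). Labels are 1-based by decreasing cluster
size; concatenating trajectories preserves per-frame provenance in the
assignment.

## Synthetic data: what it emulates and what it does not

The generator stands in for a microsecond-scale coarse-grained receptor
trajectory:

- **Geometry.** An idealized 7-helix bundle: helix axes parallel on a
  12 Å circle, C-alpha rise 1.5 Å and twist 100°/residue, all consecutive
  C-alpha distances within 3.7–3.9 Å. The 330-residue layout places the
  flexible loop at residues 231–262 (32 residues) and the lower part of
  the following helix at 267–282, so the published numbering for these
  regions applies verbatim. Loops are laid out as compact serpentines of
  tight arcs and tails as tight coils — deliberately, because an extended
  filament touching only its ±1/±2 sequence neighbors is a zero-energy
  mechanism for a distance-based network, and the elastic-network contract
  (exactly six zero modes for a connected network) requires generic,
  compact geometry, which is also what a modeled loop conformation looks
  like.
- **Statistics.** Frames are x_t = x_ref + s(t)·shift + Σ_k a_k(t)·mode_k
  + ε_t with orthonormal planted modes, a_k ~ N(0, σ_k²), a step (or
  multi-step) mean shift, isotropic per-coordinate noise, and per-frame
  rigid-body jitter applied last. One seeded generator drives everything
  with a fixed draw order, so output is bit-reproducible from (spec, seed).
- **Demo conditions.** 1000 frames at 200 ps/frame (200 ns-equivalent);
  fluctuations along the 10 slowest protein-restricted intrinsic modes
  with thermal-like 1/λ variances scaled to 8 Å² for the slowest mode;
  noise 0.3 Å per coordinate; jitter up to 5°/2 Å per frame; transition at
  70% of the run with a 25 Å (3N-norm) shift localized on the loop plus
  the adjacent helix end and orthogonalized against the planted modes (so
  the transition is a distinct degree of freedom, as a barrier crossing is
  distinct from basin fluctuations). The 70/30 split gives both states
  enough frames for stable occupancy statistics. Problem sizes (1000–5000
  frames, 330 residues, ~680 network nodes) are the package's test-scale
  choice: large enough for Monte-Carlo tolerances of a few percent,
  small enough to run interactively.

What the generator does *not* emulate: anharmonic basins, barrier
kinetics, solvent/lipid degrees of freedom, sequence-specific packing, or
correlated noise. Passing tests therefore demonstrate that the machinery
recovers planted statistical structure exactly under its own model
assumptions — not that any particular biological receptor behaves this way.
Headline numbers from trajectory-based studies of this receptor class
(variance fractions, overlap values, cluster occupancies) depend on
undeposited microsecond trajectories and are not reproducible at desk
scale; the acceptance machinery is therefore property-based throughout.

## Known limitations

- The PDB reader keeps whatever atoms the file provides but all analyses
  are C-alpha-plus-named-side-chain-atoms; no all-atom topology.
- The dense Hessian path scales to a few thousand nodes; larger systems
  would need a sparse/iterative eigensolver.
- Greedy clustering is O(n²) in frames (memory and time); tens of
  thousands of frames would need subsampling.
- Region definitions beyond the loop and lower-TM6 (helix boundaries,
  ICL2/ECL2 spans, the intracellular contact set) are configuration, not
  constants: authoritative boundary tables for a real receptor must come
  from the user.
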