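# Methods

## Model

The package identifies groups of residues that move coherently — dynamic
communities — from a single equilibrium structure, using coarse-grained
elastic network models.

**Gaussian network model.**  Each residue is a node at its C-alpha
position; pairs within a cutoff distance are joined by identical harmonic
springs.  The Kirchhoff (connectivity) matrix Γ is a weighted graph
Laplacian: Γ_ij = −γ for contacting pairs i≠j, zero otherwise, with row
sums zero.  For a connected network Γ has exactly one zero eigenvalue
(the uniform mode); residue fluctuation covariances are proportional to
the pseudoinverse restricted to the internal modes,
Γ⁻¹ = Σ_{i=2..N} λ_i⁻¹ u_i u_iᵀ.  Cross-correlations
C_ij = Γ⁻¹_ij / √(Γ⁻¹_ii Γ⁻¹_jj) are normalised covariances in [−1, 1];
the dynamic distance D_ij = √(2(1 − C_ij)) turns them into a Euclidean
metric on residues (0 = perfectly correlated, 2 = perfectly
anticorrelated).  Because C is positive semidefinite, D is isometrically
embeddable in Euclidean space — a property the test suite checks via the
double-centred Gram matrix of −D²/2.

**Community detection.**  Ward-linkage agglomerative clustering is run on
D and the tree is cut at every community count k in a sweep; each
partition is scored with the Calinski–Harabasz index, and the argmax over
k is the reported community count.  Local maxima of the CH-vs-k curve are
returned in descending order as alternative arrangements; a strong
secondary peak typically corresponds to a finer subdivision of the same
community boundaries.

**Anisotropic network model.**  For motion visualisation, residues within
a larger cutoff are connected in a 3-D network whose 3N×3N Hessian uses
the standard super-element H_ij = −γ (r_ij r_ijᵀ)/|r_ij|² for connected
pairs, with diagonal blocks enforcing translation invariance.  A
connected, non-collinear structure has exactly six zero modes (rigid
translations and rotations); the remaining eigenvectors are internal
motions, and a mode trajectory is the symmetric sweep R′ = R + s·ν.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| GNM cutoff | 7.0 | Å | C-alpha contact distance, boundary inclusive |
| γ (spring constant) | 1.0 | kT/Å² | sets the energy scale only; C and D are γ-invariant |
| k sweep | 2–20 | — | community counts explored; k_max raisable to N−1 |
| ANM cutoff | 15.0 | Å | contact distance for directional modes |
| zero-mode tolerance | 1e-8 | relative | eigenvalues below this fraction of λ_max count as rigid-body |
| trajectory amplitude | auto | Å | chosen so the most-displaced residue moves 2 Å |
| recovery threshold | 0.5 | Jaccard | overlap for a domain to count as recovered |

The 7 Å / γ=1 / 2–20 / 15 Å defaults are the published settings of the
method; the trajectory amplitude and the recovery threshold are this
package's choices (the amplitude keeps animations visually useful without
distorting geometry; the threshold is exposed as a flag because "a
separate community for a domain" admits stricter and looser readings).

## Feature representation for Ward and CH

"Clustering the distance matrix D with Ward linkage" is ambiguous: stock
agglomerative-clustering implementations with Ward accept feature vectors,
not precomputed distances.  The default mode (`rows`) therefore treats
row i of D as residue i's feature vector for both clustering and CH
scoring — the reading most likely to match results produced with such a
toolchain.  A second mode (`lw`) applies the Ward–Lance-Williams
recurrence directly to D as pairwise distances (CH still uses rows of D,
the only vector representation available).  Both modes are tested against
independent brute-force Ward implementations that recompute all merge
costs from scratch at every step.

## Numerical choices

- Symmetric eigendecomposition (`eigh`) rather than SVD for Γ and the
  Hessian; for symmetric PSD matrices the two coincide, and `eigh` returns
  ascending eigenvalues directly.  Eigenvector signs are fixed by making
  each vector's largest-magnitude component positive so cached
  intermediates are reproducible (signs cancel in the pseudoinverse).
- Exactly one GNM mode is excluded.  If two or more eigenvalues are
  numerically zero the spring network is disconnected; the run stops with
  an error naming the component count rather than silently dropping modes,
  since correlations between disconnected components are undefined in this
  model.  The analogous ANM check requires exactly six near-zero modes.
- C is clipped to [−1, 1] before the square root in D, absorbing rounding
  at the boundaries; the diagonal of C is set to exactly 1 and of D to
  exactly 0.
- CH degenerate cases use sentinels instead of exceptions so a sweep never
  aborts: zero within-cluster dispersion with separated centroids scores
  the largest finite float ("perfect separation"); identical points score
  0.  CH is undefined (error) at k=1 and k=N, so the sweep requires
  k_max < N.
- Argmax ties over k go to the smaller k (parsimony).  Ward merge-cost
  ties are resolved by the underlying nearest-neighbor-chain
  implementation, which is deterministic for fixed input; ties have
  measure zero for the float-valued distance matrices the pipeline
  produces.
- Altloc resolution keeps the highest-occupancy C-alpha (ties prefer
  altloc A, then file order); multi-model files contribute their first
  MODEL only, since the network model takes one equilibrium structure.
  HETATM records are excluded by default with an include-list override for
  modified residues; nonstandard residues in ATOM records are retained —
  the model is geometry-only.

## Synthetic fixtures

The generators in `dci.synthetic` emulate the geometric features the
pipeline depends on, not real protein chemistry:

- `make_path_chain` — collinear C-alphas whose contact graph is a path,
  giving closed-form network algebra (the 3-node chain has eigenvalues
  {0, 1, 3} and a hand-computable pseudoinverse) used as an analytic
  oracle.
- `make_two_domain` — two jittered cubic-lattice clusters (lattice
  constant 4 Å, comfortably inside the 7 Å cutoff) bridged by a 2-residue
  linker across a gap wider than the cutoff.  This plants a known
  two-community structure with a genuinely ambiguous hinge; linker
  residues are excluded from exactness checks for that reason.
- `make_block_correlation` — a block-constant PSD correlation matrix that
  bypasses the GNM entirely, isolating the clustering stage.

All randomness uses NumPy's seeded PCG64 generator, so fixtures are
bit-reproducible.  These fixtures lack real-protein features — irregular
packing densities, secondary-structure contact patterns, chain topology —
so passing tests demonstrate correctness of the algebra and the
clustering machinery, not field performance on crystal structures.  The
deposited-structure tests (community counts for calmodulin, hemoglobin,
annexin, glycyl-tRNA synthetase, the ER membrane complex and the
nicotinic receptor assemblages) cover that gap but require fetching the
PDB files with `scripts/fetch_structures.py`.

## Problem sizes

The default test and acceptance runs use fixtures of 3–50 residues and
brute-force oracle comparisons at N ≤ 10, sizes at which the naive
re-computation oracles are exact and fast.  Dense linear algebra
throughout assumes desk-scale structures (up to a few thousand residues);
a 2 500-residue complex needs one N×N and one 3N×3N eigendecomposition,
minutes on a single core.

## Known limitations

- PDB input only (no mmCIF); no symmetry/biological-assembly expansion.
- Disconnected contact graphs are an error, not a per-component analysis.
- Uniform spring constants; no distance-weighted or sequence-dependent
  variants.
- Single-mode trajectories only; no mode mixing or overlap metrics.
- The domain-recovery criterion (Jaccard ≥ threshold with greedy
  one-to-one matching) is this package's own formalisation of "a separate
  community for a domain".
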