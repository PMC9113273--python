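# dci — dynamic community identification in protein structures

Proteins move as collections of quasi-rigid groups of residues — *dynamic
communities* — and the arrangement of those communities underlies hinge
bending, allosteric communication and open–closed transitions.  `dci`
decomposes a protein structure into its dynamic communities from a single
set of coordinates, with no molecular dynamics required, and selects the
number of communities directly from the data.

## Method

Starting from the C-alpha coordinates of a structure:

1. **Gaussian network model (GNM).**  Residues within 7.0 Å are joined by
   identical springs (force constant γ = 1), giving the Kirchhoff
   connectivity matrix Γ with Γ<sub>ij</sub> = −1 for contacts and node
   degree on the diagonal.  Fluctuation covariances are the mode-truncated
   pseudoinverse Γ⁻¹ = Σ<sub>i≥2</sub> λ<sub>i</sub>⁻¹ u<sub>i</sub>u<sub>i</sub>ᵀ
   (the single zero mode of a connected network is excluded).
2. **Dynamic distances.**  Cross-correlations
   C<sub>ij</sub> = Γ⁻¹<sub>ij</sub>/√(Γ⁻¹<sub>ii</sub> Γ⁻¹<sub>jj</sub>)
   are mapped to the Euclidean dynamic distance
   D<sub>ij</sub> = √(2(1 − C<sub>ij</sub>)): perfectly correlated pairs sit at
   distance 0, perfectly anticorrelated pairs at 2.  Physically distant
   residues with correlated motions end up *close* in this metric, which is
   what lets a community span across a structure.
3. **Community detection.**  Agglomerative clustering with Ward linkage is
   applied to D (each residue's row of D is its feature vector).  The tree
   is cut at every community count k = 2…20 and each partition is scored
   with the Calinski–Harabasz index
   CH(k) = [tr(B)/(k−1)] / [tr(W)/(N−k)].  The k with the highest CH score
   is the optimal community count; secondary CH peaks are reported as
   ranked alternative arrangements.
4. **Motion visualisation (ANM).**  The anisotropic network model (15 Å
   cutoff) provides directional normal modes; conformers displaced along a
   mode, R′ = R + s·ν, are written as a multi-model PDB for animation.

## Worked example

`examples/01_identify_communities.py` builds a synthetic two-domain
structure (two packed 20-residue clusters bridged by a 2-residue linker)
and runs the full pipeline:

```
structure: two-domain-20-20, 42 residues

  k   CH score
   2      923.2  <- optimal
   3      636.3
   4      495.8
   ...
  20      114.6

optimal community count: 2
community sizes: [21, 21]
ranked CH peaks (alternative arrangements): [(2, 923.1580102699413)]
```

The CH curve peaks sharply at k = 2: each packed domain moves as one
coherent unit, and each linker residue is absorbed by the domain its
motion follows.  `examples/02_mode_motion.py` animates the inter-domain
hinge mode (the two lobes displace in opposite directions), and
`examples/03_domain_recovery.py` scores the communities against a domain
annotation (both domains recovered with Jaccard ≈ 0.95; the shortfall
from 1.0 is the genuinely ambiguous linker).

## Command line

The same pipeline is available as a `dci` executable:

```bash
dci run structure.pdb --chains A,B --kmax 20 --out results/run1
dci motion structure.pdb --mode 1 --smax AUTO --frames 11 --out motion.pdb
dci evaluate results/run1.assignments.tsv domains.tsv --threshold 0.5
```

`dci run` writes the optimal-k assignment table, per-k assignments, a JSON
report with the CH curve and ranked peaks, and a copy of the input PDB
with community indices in the B-factor column for colouring in a viewer.
HETATM records (ligands, ions, waters) are excluded by default;
`--hetatm-include MSE` retains named modified residues.

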