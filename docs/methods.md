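# Methods

## The representation

A conformation of an N-atom molecule is conventionally a list of Cartesian
coordinates, which is neither rotation- nor permutation-invariant, or a
Z-matrix of internal coordinates, which is invariant but propagates errors
down the construction chain.  The encoding implemented here — graph
information-embedded relative coordinates — describes each atom's local
geometry in a frame the molecule itself defines, and couples the frames
through the 2D bond graph so that the whole conformation can be rebuilt
exactly.

**Topology-derived quantities.**  Every bond contributes a standard
equilibrium length from an embedded table (MMFF94-style r0 values, covalent
radius sums as fallback).  Shortest bond paths under these weights give the
weighted graph distance matrix r^2D (Dijkstra).  The Coulomb matrix

    M_ii = 0.5 Z_i^2.4,    M_ij = Z_i Z_j / r_ij^2D

depends only on topology and elements; a canonical atom order S is derived
from it by sorting atoms on descending row norm of M, refining ties with
(atomic number, degree, neighbor row-norm multisets) and an iterated
neighborhood-color (Weisfeiler–Lehman style) refinement.  Atoms still tied
after refinement are automorphism-orbit members (e.g. the two hydrogens of a
CH2); inside the encoder these residual ties are broken with each atom's
sorted interatomic distance profile — a key invariant under both relabeling
and rigid motion — so that the full feature tensor of any relabeled copy of
a conformer is elementwise identical.  `canonical_order` itself remains a
pure function of topology.

**Local features.**  Atom i's frame has its origin at i, x toward its
graph-closest neighbor a, z along x × (i→b) with b the next-closest
non-collinear neighbor, and y completing the right-handed set (ties broken
by S; a neighbor collinear with a is skipped and the next one promoted).
Every atom j within three bonds of i contributes a row

    C_j^i = S2D(r_ij^2D) / r_ij^2D · (X_j^i, Y_j^i, Z_j^i),

its coordinates in i's frame scaled by the smooth cutoff S2D(r) = 1/r for
r < rcs, cosine-switched to zero between rcs = 5.0 Å and rc = 6.0 Å.
Because the scale factor is known from topology, the map is exactly
invertible wherever S2D > 0.  Rows are ordered by (r^2D, S) and zero-padded
to the dataset-wide maximum neighborhood size m; stacking all atoms in order
S yields the N×m×3 tensor.  The handedness of the frame makes mirror images
distinguishable: reflection flips the sign of every z-component.

**Decoding.**  Each local structure is inverted to neighbor positions in
its own frame.  A spanning tree of the bond graph (BFS from the canonical
root, children in S order) defines 3N−6 internal coordinates; every bond,
angle and torsion of the tree lies inside several overlapping local
structures and is therefore measured several times.  Per coordinate, the
estimates are clustered in one dimension with chaining width eps
(0.1 Å bonds, 20° angles, 20° dihedrals; circular distance for dihedrals);
only the largest cluster is kept and averaged — arithmetic mean for bonds,
circular mean for angles and torsions.  With min_samples = 1 this density
clustering is exactly the connected components of the eps-gap graph, which
in one dimension reduces to sorting and splitting at gaps larger than eps;
the implementation uses that closed form and is tested against the generic
density-clustering algorithm.  Cartesians are rebuilt by sequential natural
extension reference frame (NeRF) placement.  At zero noise every estimate
is exact, so the round trip is lossless to numerical precision; under noise
the redundancy averages errors away instead of accumulating them along the
chain, which is the source of the representation's robustness.

Ring closures are not part of the spanning tree; rebuilt rings rely on the
consistency of the tree coordinates, which is exact at zero noise, and a
diagnostic (`ring_closure_report`) exposes closure-bond deviations rather
than repairing them.  Neighbors whose graph distance exceeds rc carry zero
rows (the attenuation genuinely destroys their information); they are
excluded from decoding with a warning.  In practice this requires three
consecutive bonds longer than 2 Å, i.e. exotic chemistry.

## Noise benchmark

Three flattenings of the same conformer — the feature tensor, the
spanning-tree internal coordinates (Å, °, °), and centroid-centered
Cartesians — receive elementwise multiplicative Gaussian noise
x → x(1 + p ε).  "Percentage noise" is not further specified by the
protocol this reproduces; the multiplicative model is the natural reading
that treats Å and degree entries uniformly, and a variance-scaled additive
variant is available behind `NoiseSpec.model`.  All three decode through
the same NeRF rebuilder, isolating the representation as the experimental
variable.  Errors are measured as all-atom RMSD after Kabsch superposition
(closed-form SVD solution, proper rotations only) and as the RMSD over
canonical torsions (one per non-terminal bond, flanking atoms chosen by
canonical rank, differences wrapped to ±180°).

Expected pattern, which the acceptance suite asserts: at 2.5–10% noise the
feature-tensor route reconstructs better than both baselines in both
metrics, and its error grows only modestly with system size, whereas
internal coordinates accumulate torsion errors along the chain and
Cartesian noise scales with the molecule's radius of gyration.

## Autoencoder

The graph-conditioned autoencoder treats conformer generation as per-node
feature generation.  A message-passing network with strengthened node-edge
interactions (three rounds of edge updates from both endpoint states
followed by node updates from summed incoming messages — a communicative
message-passing variant) embeds each atom's 3-bond topological context as
h_v; node inputs are one-hot blocks for element, degree, formal charge,
chirality and hybridization, edge inputs one-hot bond types.  A dense
encoder (three hidden layers of 256, Tanh) maps each local feature F_v to a
128-dimensional latent z_v; during training z_v is perturbed
multiplicatively with 5% Gaussian noise; the decoder (same architecture
mirrored) reconstructs F_v from concat(h_v, z_v).  The loss is mean squared
error with padding rows masked out.  Training: Adam from 1e−3, halved on a
validation plateau (patience 10), early stop after 30 non-improving epochs,
hard stop when the rate falls below 1e−8; 9:1 random train/validation
split; everything is seeded and reproducible.  The networks are implemented
directly in NumPy on a small reverse-mode gradient engine
(`gierc.autodiff`) — the architecture is small enough that explicit
float64 matrix algebra on a CPU is entirely adequate.

The comparison arm is a naive whole-tensor autoencoder: the flattened
N×m×3 tensor through a dense 128-unit bottleneck with no graph
conditioning.  Its scientific role is the contrast — without per-node
decomposition the model must capture the entire layout at once, which
degrades sharply with molecule size.  The reference architecture for this
arm used 2D convolutions for feature extraction; dense layers of the same
bottleneck width are used here, which preserves the contrast mechanism
(whole-tensor input, fixed-width bottleneck) with far simpler machinery.

Latent interpolation decodes concat(h_v, (1−t) z_a + t z_b) on an equal-t
grid (20 steps → 21 structures); h_v is identical at both endpoints, so
only z is interpolated.  At t = 0 and 1 the computation coincides bitwise
with direct reconstruction.  Decoded features go through the standard
GIE-RC decoder, using the first endpoint's slab order.

## Synthetic study systems

No external data is required; the generator builds study systems that
reproduce the features the method is sensitive to:

- **24-atom small molecule** — an aromatic six-ring with a four-carbon
  saturated tail (hydrogens explicit), standing in for a PLP-sized ligand
  with a flexible, bimodal tail torsion.
- **150-atom peptide-like chain** — 21 glycine-like residues
  (N–Cα–C(=O) backbone, NH2 / COOH termini, hydrogens explicit), seeded in
  the extended all-trans conformation that chain ensembles fluctuate
  around.
- chains and branched skeletons of configurable size with deterministic
  heteroatom placement, used to diversify the round-trip tests.

Reference geometry uses table bond lengths, tetrahedral/trigonal angles
and staggered torsions; aromatic rings are seeded as exact planar hexagons.
Ensembles are drawn by sampling the most central rotatable bond from a
balanced bimodal circular mixture at 60° and 180° (σ = 10°), every other
rotatable bond unimodally about its reference value (σ = 10°), plus
Gaussian jitter on bond lengths (0.005 Å) and angles (1°), and rebuilding
through NeRF.  Substituent torsions ride along with their bond's group, so
local groups rotate rigidly.  Sampling is geometric, not thermodynamic: the
generator reproduces multi-modal torsion structure, realistic sizes and
extension, and exact graph identity across an ensemble, but not Boltzmann
weights, solvent effects or correlated backbone transitions.  Passing
benchmarks on these ensembles therefore demonstrates the properties of the
representation and models, not force-field accuracy on any real system.

Problem sizes in the shipped tests and acceptance runs (2,000 conformers
for the small-system autoencoder, 300 for the 150-atom pair, 10 structure
pairs with 3–30 noise repeats) are the package's chosen desk-scale study
conditions; all are parameters of the public API.

## Numerical choices and edge cases

- Angles are kept in (0, 180)°; a consensus angle is clamped away from the
  degenerate endpoints by 1e−3°, and NeRF refuses exactly collinear
  reference triples ("degenerate placement").
- Local frames require |sin| > 1e−3 between the two reference directions;
  collinear candidates are skipped in topological order, and a fully
  collinear neighborhood is an error naming the atom.
- Dihedral consensus ties (equal cluster sizes) resolve to the cluster with
  the smallest member value; all tie-breaks in the package are
  deterministic.
- Encoding refuses a padding width smaller than the molecule requires
  rather than truncating.
- The feature container records the graph fingerprint (elements, charges,
  bonds, bond-table version); decoding against the wrong molecule or a
  different table version is an error.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`.

## Known limitations

- Automorphism-orbit slab assignment depends (invariantly) on the
  conformer's geometry, so orbit atoms may occupy different slab positions
  in different conformers of an ensemble; node features and graph
  embeddings are identical within an orbit, so downstream models are
  unaffected.
- Ring-closure deviations under heavy noise are reported, not repaired; no
  energy model exists anywhere in the package, so decoded structures are
  geometrically, not thermodynamically, plausible.
- The naive-AE arm is a dense stand-in for a convolutional reference
  design, adequate for the size-scaling contrast but not a replication of
  that architecture.
- Generalization across molecules (decoding a graph never seen in
  training) is structurally supported — the decoder conditions on h_v —
  but is not validated here.
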