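# gierc

Reversible, SE(3)- and exchange-invariant encoding of molecular 3D
conformations — graph information-embedded relative coordinates — together
with a graph-constrained autoencoder that turns conformer generation into a
per-node feature generation problem.

## The problem

Generative models for molecular conformations need a coordinate
representation that (i) does not change when the molecule is translated,
rotated, or its atoms are relabeled, (ii) can be converted back to 3D
coordinates without loss, and (iii) degrades gracefully when a model
reconstructs it imperfectly.  Cartesian coordinates fail (i); internal
coordinates (Z-matrices) satisfy (i) and (ii) but amplify errors — a small
torsion error near the root of the construction chain swings the whole far
end of the molecule.  This package implements a representation that
satisfies all three, for anyone building conformer generators, sampling
tools, or training-set augmentation pipelines for neural network force
fields.

## The representation

For each atom *i*, a local right-handed frame is built from its two
graph-closest neighbors *a*, *b*.  Every atom *j* within three bonds of *i*
contributes a row

&nbsp;&nbsp;&nbsp;&nbsp;C_j^i = S2D(r_ij^2D)/r_ij^2D · (X_j^i, Y_j^i, Z_j^i),

where (X, Y, Z) are *j*'s coordinates in *i*'s frame, r^2D is the weighted
graph distance (shortest bond path under standard bond lengths), and S2D is
a smooth cutoff (1/r below 5 Å, cosine-switched to zero at 6 Å).  Rows are
ordered by graph distance with ties broken by a canonical atom order S
derived from the Coulomb matrix M (M_ii = 0.5 Z^2.4, M_ij = Z_iZ_j/r_ij^2D);
stacking all atoms in order S yields an N×m×3 tensor.  Because the scale
factors are known from topology alone, every local structure is exactly
invertible; overlapping local structures measure each spanning-tree internal
coordinate several times, and decoding keeps the largest density cluster of
estimates, averages it, and rebuilds Cartesians by sequential (NeRF)
placement.  At zero noise the round trip is exact; under noise the
redundancy averages errors away instead of accumulating them.

The autoencoder encodes each per-atom feature F_v to a 128-dimensional
latent z_v and reconstructs it from concat(h_v, z_v), where h_v is a
message-passing embedding of the atom's 3-bond graph context — so the graph
carries the chemistry and the latent carries only the conformational
degrees of freedom.  Linear interpolation in z decodes to smooth
conformational transitions.

## Worked example

```python
from gierc import GraphContext, encode, decode, kabsch_rmsd, run_noise_benchmark
from gierc.synth import TemplateSpec, default_ensemble_spec, make_template, sample_ensemble

# 24-atom ring-plus-tail molecule with a bimodal tail torsion
g, ref = make_template(TemplateSpec(kind="ring_plus_tail", n_heavy=10, seed=3))
ctx = GraphContext(g)
confs = sample_ensemble(g, ref, default_ensemble_spec(g, ref, 10, seed=1))

f = encode(confs[0], ctx)                      # tensor, shape (24, 16, 3)
print(round(kabsch_rmsd(confs[0], decode(f, ctx)), 10))

df = run_noise_benchmark(confs, ctx, levels=(0.0, 5.0, 10.0), n_pairs=10, seed=7)
print(df[["noise_percent", "rmsd_gie_rc", "rmsd_internal", "rmsd_cartesian"]].round(3))
```

prints

```
0.0
   noise_percent  rmsd_gie_rc  rmsd_internal  rmsd_cartesian
0            0.0        0.000          0.000           0.000
1            5.0        0.063          0.344           0.156
2           10.0        0.165          0.628           0.278
```

Row by row: the zero-noise round trip is lossless for all three
representations; at 5% and 10% multiplicative noise on the encoded vectors,
the GIE-RC reconstruction error (0.06 / 0.17 Å) stays several-fold below
the internal-coordinate (0.34 / 0.63 Å) and Cartesian (0.16 / 0.28 Å)
baselines — the advantage that motivates the representation.  The same
pattern holds, more dramatically, for a 150-atom peptide-like chain.

A CLI mirrors the library:

```sh
gierc gen-synth spec.json ensemble.sdf --seed 7   # synthetic ensemble + manifest
gierc encode ensemble.sdf feat.npz                # conformer -> feature tensor
gierc decode feat.npz ensemble.sdf decoded.sdf    # tensor -> 3D, prints RMSD
gierc bench-noise ensemble.sdf bench.csv --levels 0,2.5,5,10
gierc cluster ensemble.sdf                        # torsion-space DBSCAN
gierc train ensemble.sdf model.npz --epochs 50    # graph-conditioned AE
gierc interpolate model.npz ensemble.sdf path.sdf --steps 20
```

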