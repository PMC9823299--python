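"""The GIE-RC codec: attenuation, local frames, consensus, round trips."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.cluster import DBSCAN

from gierc.bench import kabsch_rmsd, torsion_rmsd
from gierc.codec import (
    GraphContext,
    attenuation,
    build_local_frame,
    circular_mean,
    cluster_1d,
    consensus_internal_coords,
    decode,
    encode,
    encode_local,
    extract_internal_coords,
    local_positions_from_feature,
    ICEstimates,
)
from gierc.internal import (
    Conformer,
    bond_angle,
    bond_length,
    build_tree,
    dihedral_angle,
)
from gierc.molgraph import MolecularGraph
from gierc.synth import TemplateSpec, default_ensemble_spec, make_template, sample_ensemble


class TestAttenuation:
    def test_inverse_distance_branch(self):
        assert attenuation(2.0, 5.0, 6.0) == pytest.approx(0.5)

    def test_zero_beyond_outer_cutoff(self):
        assert attenuation(6.0, 5.0, 6.0) == 0.0
        assert attenuation(7.5, 5.0, 6.0) == 0.0

    def test_switching_region_value(self):
        # midpoint of the switch: cos(pi/2) = 0, so (1/5.5)·0.5
        assert attenuation(5.5, 5.0, 6.0) == pytest.approx(1 / 5.5 * 0.5, abs=1e-12)

    def test_continuity_at_cutoffs(self):
        for r0 in (5.0, 6.0):
            lo = attenuation(r0 - 1e-9, 5.0, 6.0)
            hi = attenuation(r0 + 1e-9, 5.0, 6.0)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            attenuation(-1.0, 5.0, 6.0)
        with pytest.raises(ValueError):
            attenuation(2.0, 6.0, 5.0)


class TestLocalFrame:
    def test_canonical_configuration_gives_identity(self):
        # O is graph-closer than C, so a=1 and b=2 unambiguously
        g = MolecularGraph(
            atomic_numbers=(6, 8, 6, 6),
            bonds=((0, 1, 1), (0, 2, 1), (2, 3, 1)),
        )
        ctx = GraphContext(g)
        coords = np.array([
            [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0], [0.0, 2.5, 1.0],
        ])
        conf = Conformer(coords=coords, graph=g)
        s = ctx.order_for(conf)
        frame = build_local_frame(conf, ctx, s, 0)
        assert frame.ref_a == 1 and frame.ref_b == 2
        np.testing.assert_allclose(frame.axes, np.eye(3), atol=1e-12)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0)

    def test_equivariance_under_rotation(self, small_ctx, small_conformers, rng):
        conf = small_conformers[0]
        s = small_ctx.order_for(conf)
        f0 = build_local_frame(conf, small_ctx, s, 0)
        rot = Rotation.random(random_state=7).as_matrix()
        conf_r = Conformer(coords=conf.coords @ rot.T + 3.0, graph=small_ctx.g)
        fr = build_local_frame(conf_r, small_ctx, s, 0)
        np.testing.assert_allclose(fr.axes, f0.axes @ rot.T, atol=1e-10)

    def test_collinear_neighbor_promoted(self):
        # atom 2 sits exactly on the 0→1 axis; atom 3 must be promoted to b
        g = MolecularGraph(
            atomic_numbers=(6, 6, 6, 6),
            bonds=((0, 1, 1), (1, 2, 1), (2, 3, 1)),
        )
        ctx = GraphContext(g)
        coords = np.array([
            [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [3.0, 0.0, 0.0], [3.5, 1.4, 0.0],
        ])
        conf = Conformer(coords=coords, graph=g)
        s = ctx.order_for(conf)
        frame = build_local_frame(conf, ctx, s, 0)
        assert frame.ref_a == 1
        assert frame.ref_b == 3

    def test_fully_collinear_raises(self):
        g = MolecularGraph(
            atomic_numbers=(6, 6, 6, 6),
            bonds=((0, 1, 1), (1, 2, 1), (2, 3, 1)),
        )
        ctx = GraphContext(g)
        coords = np.array([[float(k) * 1.5, 0.0, 0.0] for k in range(4)])
        conf = Conformer(coords=coords, graph=g)
        s = ctx.order_for(conf)
        with pytest.raises(ValueError, match="degenerate local frame"):
            build_local_frame(conf, ctx, s, 0)


class TestLocalFeature:
    def test_scaling_matches_attenuation_over_distance(self, small_ctx, small_conformers):
        conf = small_conformers[0]
        s = small_ctx.order_for(conf)
        i = s.order[0]
        feat = encode_local(conf, small_ctx, s, i, m=small_ctx.max_neighborhood_size())
        frame = build_local_frame(conf, small_ctx, s, i)
        for k, j in enumerate(feat.neighbor_ids):
            r = small_ctx.r2d.values[i, j]
            local = frame.axes @ (conf.coords[j] - conf.coords[i])
            np.testing.assert_allclose(
                feat.rc[k], attenuation(r) / r * local, atol=1e-12
            )

    def test_padding_rows_exactly_zero(self, small_ctx, small_conformers):
        conf = small_conformers[0]
        s = small_ctx.order_for(conf)
        m = small_ctx.max_neighborhood_size() + 3
        for i in range(small_ctx.g.n_atoms):
            feat = encode_local(conf, small_ctx, s, i, m=m)
            assert np.all(feat.rc[len(feat.neighbor_ids):] == 0.0)

    def test_local_positions_invert_encoding(self, small_ctx, small_conformers):
        conf = small_conformers[1]
        s = small_ctx.order_for(conf)
        m = small_ctx.max_neighborhood_size()
        for i in range(small_ctx.g.n_atoms):
            feat = encode_local(conf, small_ctx, s, i, m=m)
            pos = local_positions_from_feature(feat, small_ctx, i)
            frame = build_local_frame(conf, small_ctx, s, i)
            for j in feat.neighbor_ids:
                expected = frame.axes @ (conf.coords[j] - conf.coords[i])
                np.testing.assert_allclose(pos[j], expected, atol=1e-10)

    def test_neighbor_beyond_outer_cutoff_excluded(self, caplog):
        # three consecutive P–S bonds exceed rc = 6 Å in graph distance
        g = MolecularGraph(
            atomic_numbers=(16, 15, 16, 15),
            bonds=((0, 1, 1), (1, 2, 1), (2, 3, 1)),
        )
        ctx = GraphContext(g)
        assert ctx.r2d.values[0, 3] > ctx.rc
        coords = np.array([
            [0.0, 0.0, 0.0], [2.0, 0.5, 0.0], [3.5, -0.9, 0.4], [5.5, 0.2, -0.6],
        ])
        conf = Conformer(coords=coords, graph=g)
        s = ctx.order_for(conf)
        feat = encode_local(conf, ctx, s, 0, m=3)
        k = feat.neighbor_ids.index(3)
        assert np.all(feat.rc[k] == 0.0)
        with caplog.at_level("WARNING"):
            pos = local_positions_from_feature(feat, ctx, 0)
        assert 3 not in pos
        assert "unrecoverable" in caplog.text


class TestConsensusClustering:
    def test_identical_estimates_pass_through(self):
        groups = cluster_1d([1.50, 1.50, 1.50], eps=0.1)
        assert groups == [[0, 1, 2]]

    def test_outlier_dropped(self):
        vals = [1.50, 1.51, 1.49, 3.20]
        groups = cluster_1d(vals, eps=0.1)
        assert sorted(groups[0]) == [0, 1, 2]
        assert float(np.mean([vals[k] for k in groups[0]])) == pytest.approx(1.50)

    def test_circular_wraparound_merges(self):
        groups = cluster_1d([179.0, -179.0], eps=20.0, circular=True)
        assert len(groups) == 1
        assert abs(abs(circular_mean([179.0, -179.0])) - 180.0) < 1e-9

    def test_matches_sklearn_dbscan_linear(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 5, size=rng.integers(2, 40))
            eps = rng.uniform(0.05, 1.0)
            mine = cluster_1d(vals, eps)
            labels = DBSCAN(eps=eps, min_samples=1).fit(vals.reshape(-1, 1)).labels_
            mine_sets = {frozenset(grp) for grp in mine}
            theirs = {
                frozenset(np.flatnonzero(labels == lab).tolist())
                for lab in set(labels)
            }
            assert mine_sets == theirs

    def test_matches_sklearn_dbscan_circular(self, rng):
        for _ in range(20):
            vals = rng.uniform(-180, 180, size=rng.integers(2, 40))
            eps = rng.uniform(5, 60)
            mine = cluster_1d(vals, eps, circular=True)
            d = np.abs(vals[:, None] - vals[None, :])
            d = np.minimum(d, 360 - d)
            labels = DBSCAN(eps=eps, min_samples=1, metric="precomputed").fit(d).labels_
            mine_sets = {frozenset(grp) for grp in mine}
            theirs = {
                frozenset(np.flatnonzero(labels == lab).tolist())
                for lab in set(labels)
            }
            assert mine_sets == theirs

    def test_single_estimate_passes_unchanged(self):
        est = ICEstimates(
            records=((0,), (1, 0), (2, 1, 0), (3, 2, 1, 0)),
            bonds=[[(1.5, 0)], [(1.4, 0)], [(1.3, 0)]],
            angles=[[(109.0, 0)], [(112.0, 0)]],
            dihedrals=[[(-60.0, 0)]],
        )
        ics = consensus_internal_coords(est)
        np.testing.assert_allclose(ics.bond_lengths, [1.5, 1.4, 1.3])
        np.testing.assert_allclose(ics.dihedrals, [-60.0])


class TestEstimateExtraction:
    def _local_positions(self, conf, ctx):
        s = ctx.order_for(conf)
        m = ctx.max_neighborhood_size()
        out = {}
        for i in range(ctx.g.n_atoms):
            feat = encode_local(conf, ctx, s, i, m=m)
            out[i] = local_positions_from_feature(feat, ctx, i)
        return out, s

    def test_zero_noise_estimates_match_cartesian_oracle(self, small_ctx, small_conformers):
        conf = small_conformers[2]
        pos, s = self._local_positions(conf, small_ctx)
        records = build_tree(small_ctx.g, s)
        est = extract_internal_coords(pos, records)
        c = conf.coords
        bi = ai = di = 0
        for rec in records:
            if len(rec) >= 2:
                truth = bond_length(c, rec[0], rec[1])
                for v, _src in est.bonds[bi]:
                    assert v == pytest.approx(truth, abs=1e-9)
                bi += 1
            if len(rec) >= 3:
                truth = bond_angle(c, rec[0], rec[1], rec[2])
                for v, _src in est.angles[ai]:
                    assert v == pytest.approx(truth, abs=1e-9)
                ai += 1
            if len(rec) == 4:
                truth = dihedral_angle(c, *rec)
                for v, _src in est.dihedrals[di]:
                    assert abs((v - truth + 180) % 360 - 180) < 1e-9
                di += 1

    def test_dihedral_observed_from_both_central_atoms(self, chain_system):
        g, ref = chain_system
        ctx = GraphContext(g)
        pos, s = self._local_positions(ref, ctx)
        records = build_tree(g, s)
        est = extract_internal_coords(pos, records)
        di = 0
        for rec in records:
            if len(rec) == 4:
                centers = {src for _v, src in est.dihedrals[di]}
                hops = ctx.hops
                # both central-bond atoms see the whole quad
                if all(hops[rec[1], x] <= 3 for x in rec) and all(
                    hops[rec[2], x] <= 3 for x in rec
                ):
                    assert rec[1] in centers and rec[2] in centers
                di += 1

    def test_central_bonds_have_more_estimates_than_terminal(self):
        g, ref = make_template(TemplateSpec(kind="chain", n_heavy=12, include_h=False, seed=0))
        ctx = GraphContext(g)
        pos, s = self._local_positions(ref, ctx)
        records = build_tree(g, s)
        est = extract_internal_coords(pos, records)
        counts = {}
        bi = 0
        for rec in records:
            if len(rec) >= 2:
                counts[tuple(sorted(rec[:2]))] = len(est.bonds[bi])
                bi += 1
        ends = [b for b in counts if 0 in b or g.n_atoms - 1 in b]
        mids = [b for b in counts if b not in ends]
        assert max(counts[b] for b in mids) >= max(counts[b] for b in ends)


@pytest.mark.parametrize(
    "kind,n_heavy",
    [("chain", 8), ("branched", 10), ("ring_plus_tail", 10), ("peptide_like", 24)],
)
def test_roundtrip_lossless_per_topology(kind, n_heavy):
    g, ref = make_template(TemplateSpec(kind=kind, n_heavy=n_heavy, seed=3))
    ctx = GraphContext(g)
    confs = sample_ensemble(g, ref, default_ensemble_spec(g, ref, 3, seed=5))
    for conf in confs:
        dec = decode(encode(conf, ctx), ctx)
        assert kabsch_rmsd(conf, dec) < 1e-6
        assert torsion_rmsd(conf, dec, ctx) < 1e-6


def test_decode_ignores_rigid_placement_of_input(small_ctx, small_conformers):
    conf = small_conformers[0]
    rot = Rotation.random(random_state=3).as_matrix()
    moved = Conformer(coords=conf.coords @ rot.T + 100.0, graph=small_ctx.g)
    d1 = decode(encode(conf, small_ctx), small_ctx)
    d2 = decode(encode(moved, small_ctx), small_ctx)
    np.testing.assert_allclose(d1.coords, d2.coords, atol=1e-8)


def test_encode_shape_and_m_contract(small_ctx, small_conformers):
    conf = small_conformers[0]
    f = encode(conf, small_ctx)
    assert f.features.shape == (24, small_ctx.max_neighborhood_size(), 3)
    f2 = encode(conf, small_ctx, m=f.m + 4)
    assert f2.features.shape == (24, f.m + 4, 3)
    with pytest.raises(ValueError, match="too small"):
        encode(conf, small_ctx, m=2)


def test_decode_rejects_wrong_molecule(small_ctx, small_conformers, chain_system):
    f = encode(small_conformers[0], small_ctx)
    other = GraphContext(chain_system[0])
    with pytest.raises(ValueError, match="different molecule"):
        decode(f, other)
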