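"""Featurization, message passing, autoencoder training, clustering,
interpolation."""

import numpy as np
import pytest

from gierc.autodiff import Tensor
from gierc.codec import GraphContext
from gierc.graph_ae import (
    GraphAE,
    NaiveAE,
    NodeEdgeFeatures,
    TrainConfig,
    cluster_conformers,
    decode_node_feature,
    encode_ensemble,
    featurize,
    interpolate,
    reconstruct,
    torsion_matrix,
    train_graph_ae,
    train_naive_ae,
)
from gierc.internal import wrap_degrees
from gierc.molgraph import MolecularGraph
from gierc.synth import (
    EnsembleSpec,
    TemplateSpec,
    default_ensemble_spec,
    key_rotatable_bond,
    make_template,
    sample_ensemble,
)


class TestFeaturize:
    def test_one_hot_blocks_sum_to_one(self, small_ctx):
        f = featurize(small_ctx.g, small_ctx)
        # five node blocks, one edge block
        widths = [7, 5, 4, 4, 5]
        off = 0
        for w in widths:
            np.testing.assert_array_equal(f.node[:, off : off + w].sum(axis=1), 1.0)
            off += w
        np.testing.assert_array_equal(f.edge.sum(axis=1), 1.0)

    def test_symmetric_atoms_have_identical_features(self, small_ctx):
        f = featurize(small_ctx.g, small_ctx)
        colors = [small_ctx.base_order.colors[a] for a in small_ctx.base_order.order]
        for i in range(len(colors)):
            for j in range(i + 1, len(colors)):
                if colors[i] == colors[j]:
                    np.testing.assert_array_equal(f.node[i], f.node[j])

    def test_vocabulary_roundtrip(self, small_ctx):
        g = small_ctx.g
        f = featurize(g, small_ctx)
        for pos, atom in enumerate(small_ctx.base_order.order):
            z, deg, chg, chi, hyb = decode_node_feature(f.node[pos])
            assert z == g.atomic_numbers[atom]
            assert deg == g.degrees[atom]
            assert chg == g.formal_charges[atom]


def _path_features(n, hidden_blocks=4, flip_node=None):
    """Hand-built path-graph features for receptive-field tests."""
    node = np.zeros((n, hidden_blocks))
    node[np.arange(n), np.arange(n) % hidden_blocks] = 1.0
    if flip_node is not None:
        node[flip_node] = 1.0 - node[flip_node]
    src, dst = [], []
    for k in range(n - 1):
        src += [k, k + 1]
        dst += [k + 1, k]
    edge = np.ones((len(src), 2)) * 0.5
    return NodeEdgeFeatures(node=node, edge=edge,
                            src=np.array(src), dst=np.array(dst))


class TestMessagePassing:
    def test_receptive_field_is_three_bonds(self):
        cfg = TrainConfig(hidden=16, latent_dim=8, seed=0)
        base = _path_features(10)
        pert = _path_features(10, flip_node=0)
        m1 = GraphAE(base, in_dim=6, cfg=cfg)
        m2 = GraphAE(pert, in_dim=6, cfg=cfg)
        h1 = m1.graph_embeddings().data
        h2 = m2.graph_embeddings().data
        assert np.max(np.abs(h1[:4] - h2[:4])) > 1e-6   # within 3 bonds: affected
        np.testing.assert_allclose(h1[4:], h2[4:], atol=1e-12)  # beyond: untouched

    def test_automorphic_atoms_get_equal_embeddings(self):
        # ethane-like skeleton: two equivalent carbons, six equivalent H
        g = MolecularGraph(
            atomic_numbers=(6, 6, 1, 1, 1, 1, 1, 1),
            bonds=((0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1),
                   (1, 5, 1), (1, 6, 1), (1, 7, 1)),
        )
        ctx = GraphContext(g)
        feats = featurize(g, ctx)
        model = GraphAE(feats, in_dim=9, cfg=TrainConfig(hidden=32, latent_dim=8, seed=1))
        h = model.graph_embeddings().data
        colors = [ctx.base_order.colors[a] for a in ctx.base_order.order]
        for i in range(len(colors)):
            for j in range(i + 1, len(colors)):
                if colors[i] == colors[j]:
                    np.testing.assert_allclose(h[i], h[j], atol=1e-6)

    def test_forward_is_deterministic_given_seed(self, small_ctx):
        feats = featurize(small_ctx.g, small_ctx)
        m = small_ctx.max_neighborhood_size()
        x = np.random.default_rng(0).normal(size=(small_ctx.g.n_atoms, m * 3))
        cfg = TrainConfig(hidden=32, latent_dim=16, seed=5)
        out1 = GraphAE(feats, in_dim=m * 3, cfg=cfg).forward(x).data
        out2 = GraphAE(feats, in_dim=m * 3, cfg=cfg).forward(x).data
        np.testing.assert_array_equal(out1, out2)


@pytest.fixture(scope="module")
def tiny_dataset():
    g, ref = make_template(TemplateSpec(kind="chain", n_heavy=6, include_h=False, seed=2))
    ctx = GraphContext(g)
    spec = default_ensemble_spec(g, ref, 60, seed=3)
    confs = sample_ensemble(g, ref, spec)
    x, headers = encode_ensemble(confs, ctx)
    return ctx, confs, x, headers


class TestTraining:
    def test_validation_loss_improves(self, tiny_dataset):
        ctx, _, x, _ = tiny_dataset
        cfg = TrainConfig(hidden=32, latent_dim=16, max_epochs=15, seed=0)
        _, log = train_graph_ae(x, ctx, cfg)
        assert log["best_val_loss"] < log["val_loss"][0]

    def test_fixed_seed_reproduces_loss(self, tiny_dataset):
        ctx, _, x, _ = tiny_dataset
        cfg = TrainConfig(hidden=32, latent_dim=16, max_epochs=4, seed=7)
        _, log1 = train_graph_ae(x, ctx, cfg)
        _, log2 = train_graph_ae(x, ctx, cfg)
        assert log1["val_loss"] == pytest.approx(log2["val_loss"], abs=1e-6)

    def test_memorization_with_ample_latent_and_no_noise(self, tiny_dataset):
        # latent >= input dim and no latent noise: the AE can act as identity
        ctx, _, x, _ = tiny_dataset
        in_dim = x.shape[2] * 3
        cfg = TrainConfig(hidden=64, latent_dim=max(64, in_dim),
                          noise_percent=0.0, max_epochs=150,
                          plateau_patience=20, early_stop=150, seed=0)
        _, log = train_graph_ae(x, ctx, cfg)
        assert min(log["train_loss"]) < 1e-4

    def test_naive_ae_trains_and_reproduces(self, tiny_dataset):
        ctx, _, x, _ = tiny_dataset
        cfg = TrainConfig(latent_dim=16, max_epochs=4, seed=3)
        m1, log1 = train_naive_ae(x, ctx, cfg)
        m2, log2 = train_naive_ae(x, ctx, cfg)
        assert log1["val_loss"] == pytest.approx(log2["val_loss"], abs=1e-6)
        rec = reconstruct(m1, x[0])
        assert rec.shape == x[0].shape

    def test_model_checkpoint_roundtrip(self, tiny_dataset, tmp_path):
        from gierc.models import load_model, save_model

        ctx, _, x, _ = tiny_dataset
        cfg = TrainConfig(hidden=32, latent_dim=16, max_epochs=2, seed=0)
        model, _ = train_graph_ae(x, ctx, cfg)
        path = tmp_path / "model.npz"
        save_model(model, ctx, path)
        loaded = load_model(path, ctx)
        np.testing.assert_array_equal(
            reconstruct(model, x[0]), reconstruct(loaded, x[0])
        )

    def test_divergence_aborts(self, tiny_dataset):
        ctx, _, x, _ = tiny_dataset
        cfg = TrainConfig(hidden=16, latent_dim=8, max_epochs=5, lr=1e6, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            train_graph_ae(x * 1e3, ctx, cfg)


class TestClusterConformers:
    def test_two_modes_two_clusters(self, small_system, small_ctx):
        g, ref = small_system
        confs = sample_ensemble(g, ref, default_ensemble_spec(g, ref, 100, seed=5))
        labels = cluster_conformers(confs, small_ctx, eps=30.0, min_samples=5)
        assert len(set(labels) - {-1}) == 2

    def test_single_tight_ensemble_one_cluster(self, small_system, small_ctx):
        g, ref = small_system
        bond = key_rotatable_bond(g)
        spec = EnsembleSpec(n_conformers=40,
                            torsion_modes={bond: [(180.0, 3.0, 1.0)]}, seed=6)
        confs = sample_ensemble(g, ref, spec)
        labels = cluster_conformers(confs, small_ctx, eps=30.0, min_samples=3)
        assert set(labels) == {0}

    def test_agrees_with_connected_components_oracle(self, small_system, small_ctx):
        g, ref = small_system
        confs = sample_ensemble(g, ref, default_ensemble_spec(g, ref, 80, seed=7))
        eps = 25.0
        labels = cluster_conformers(confs, small_ctx, eps=eps, min_samples=1)
        t = torsion_matrix(confs, small_ctx)
        diff = wrap_degrees(t[:, None, :] - t[None, :, :])
        dist = np.sqrt((diff**2).sum(-1))
        # union-find over the eps-graph
        parent = list(range(len(confs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(confs)):
            for j in range(i + 1, len(confs)):
                if dist[i, j] <= eps:
                    parent[find(i)] = find(j)
        comp = {}
        for i in range(len(confs)):
            comp.setdefault(find(i), set()).add(i)
        ours = {frozenset(np.flatnonzero(labels == lab).tolist()) for lab in set(labels)}
        assert ours == {frozenset(c) for c in comp.values()}

    def test_min_cluster_size_filters(self, small_system, small_ctx):
        g, ref = small_system
        confs = sample_ensemble(g, ref, default_ensemble_spec(g, ref, 60, seed=8))
        labels = cluster_conformers(confs, small_ctx, eps=30.0, min_samples=2,
                                    min_cluster_size=1000)
        assert set(labels) == {-1}


class TestInterpolation:
    def test_endpoints_match_direct_reconstruction_bitwise(self, trained_small_ae, small_ctx):
        model = trained_small_ae["model"]
        confs = trained_small_ae["confs"]
        path = interpolate(model, small_ctx, confs[0], confs[1], steps=4)
        assert len(path) == 5
        from gierc.codec import GIERCM, decode, encode

        m = small_ctx.max_neighborhood_size()
        for t, conf, endpoint in ((0.0, confs[0], path[0]), (1.0, confs[1], path[-1])):
            f = encode(conf, small_ctx, m=m)
            rec = reconstruct(model, f.features)
            direct = decode(
                GIERCM(features=rec, order=f.order, m=m, rcs=f.rcs, rc=f.rc,
                       fingerprint=f.fingerprint),
                small_ctx,
            )
            # the t=0 path must be the same computation, bit for bit
            if t == 0.0:
                np.testing.assert_array_equal(endpoint[1].coords, direct.coords)

    def test_interior_points_decode(self, trained_small_ae, small_ctx):
        model = trained_small_ae["model"]
        confs = trained_small_ae["confs"]
        path = interpolate(model, small_ctx, confs[0], confs[5], steps=10)
        decoded = [c for _, c in path if c is not None]
        assert len(decoded) >= 9
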