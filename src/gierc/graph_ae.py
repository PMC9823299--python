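"""Graph-constrained autoencoder over per-node GIE-RC features.

Two encoders meet at the bottleneck: a message-passing network over the
molecular graph produces a per-node embedding h_v (topology only), and a
dense encoder maps each node's local structure feature F_v to a latent code
z_v.  The decoder reconstructs F_v from concat(h_v, z_v); the graph
embedding conditions the reconstruction so that only the conformational
degrees of freedom have to live in z.  A naive whole-tensor autoencoder
(no graph conditioning) serves as the comparison arm.

Implemented in NumPy on a small reverse-mode gradient engine; training uses
Adam with a halve-on-plateau learning-rate schedule, Tanh activations and a
masked MSE loss that ignores zero-padding rows.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .autodiff import Adam, Linear, Tensor, concat, gather, masked_mse, scatter_add
from .codec import GIERCM, GraphContext, decode, encode
from .internal import Conformer, canonical_torsions, torsion_values, wrap_degrees
from .molgraph import MolecularGraph

__all__ = [
    "NodeEdgeFeatures",
    "TrainConfig",
    "GraphAE",
    "NaiveAE",
    "featurize",
    "decode_node_feature",
    "encode_ensemble",
    "train_graph_ae",
    "train_naive_ae",
    "reconstruct",
    "reconstruction_errors",
    "interpolate",
    "cluster_conformers",
    "torsion_matrix",
]

_Z_VOCAB = [1, 6, 7, 8, 15, 16]
_DEG_VOCAB = [1, 2, 3, 4]
_CHG_VOCAB = [-1, 0, 1]
_CHI_VOCAB = ["none", "R", "S"]
_HYB_VOCAB = ["s", "sp", "sp2", "sp3"]
_BT_VOCAB = [1.0, 1.5, 2.0, 3.0]


def _one_hot(value, vocab):
    v = np.zeros(len(vocab) + 1)
    v[vocab.index(value) if value in vocab else len(vocab)] = 1.0
    return v


@dataclass
class NodeEdgeFeatures:
    """One-hot node blocks (element, degree, charge, chirality,
    hybridization) in canonical slab order, plus directed edge features and
    their endpoint indices (also canonical positions)."""

    node: np.ndarray
    edge: np.ndarray
    src: np.ndarray
    dst: np.ndarray


def featurize(g: MolecularGraph, ctx: GraphContext) -> NodeEdgeFeatures:
    order = ctx.base_order.order
    rank = ctx.base_order.rank
    deg = g.degrees
    node = np.stack([
        np.concatenate([
            _one_hot(g.atomic_numbers[a], _Z_VOCAB),
            _one_hot(deg[a], _DEG_VOCAB),
            _one_hot(g.formal_charges[a], _CHG_VOCAB),
            _one_hot(g.chirality_tags[a], _CHI_VOCAB),
            _one_hot(g.hybridizations[a], _HYB_VOCAB),
        ])
        for a in order
    ])
    src, dst, ef = [], [], []
    for i, j, o in g.bonds:
        for u, v in ((i, j), (j, i)):
            src.append(rank[u])
            dst.append(rank[v])
            ef.append(_one_hot(float(o), _BT_VOCAB))
    return NodeEdgeFeatures(node=node, edge=np.stack(ef),
                            src=np.array(src), dst=np.array(dst))


def decode_node_feature(row: np.ndarray):
    """Invert the node one-hot concatenation back to its categorical tuple
    (an OTHER slot decodes to None)."""
    out = []
    off = 0
    for vocab in (_Z_VOCAB, _DEG_VOCAB, _CHG_VOCAB, _CHI_VOCAB, _HYB_VOCAB):
        block = row[off : off + len(vocab) + 1]
        k = int(np.argmax(block))
        out.append(vocab[k] if k < len(vocab) else None)
        off += len(vocab) + 1
    return tuple(out)


@dataclass
class TrainConfig:
    latent_dim: int = 128
    hidden: int = 256
    mp_layers: int = 3
    noise_percent: float = 0.05
    lr: float = 1e-3
    lr_min: float = 1e-8
    plateau_patience: int = 10
    early_stop: int = 30
    max_epochs: int = 200
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.latent_dim, self.hidden, self.max_epochs, self.batch_size) <= 0:
            raise ValueError("config sizes must be positive")


class _MLP:
    def __init__(self, dims, rng, final_linear=True):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_linear = final_linear

    def __call__(self, x):
        for k, layer in enumerate(self.layers):
            x = layer(x)
            if k < len(self.layers) - 1 or not self.final_linear:
                x = x.tanh()
        return x

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]


class GraphAE:
    """Per-node autoencoder conditioned on message-passing graph embeddings.

    Message passing alternates edge updates (from both endpoint states and
    the previous edge state) with node updates (from the node state and the
    sum of incoming edge messages); after ``mp_layers`` rounds the embedding
    of a node covers exactly that many bonds of context.
    """

    variant = "graph_ae"

    def __init__(self, feats: NodeEdgeFeatures, in_dim: int, cfg: TrainConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.feats = feats
        h = cfg.hidden
        self.node_embed = Linear(feats.node.shape[1], h, rng)
        self.edge_embed = Linear(feats.edge.shape[1], h, rng)
        self.edge_upd = [Linear(3 * h, h, rng) for _ in range(cfg.mp_layers)]
        self.node_upd = [Linear(2 * h, h, rng) for _ in range(cfg.mp_layers)]
        self.encoder = _MLP([in_dim, h, h, h, cfg.latent_dim], rng)
        self.decoder = _MLP([h + cfg.latent_dim, h, h, h, in_dim], rng)

    @property
    def params(self):
        out = self.node_embed.params + self.edge_embed.params
        for layer in self.edge_upd + self.node_upd:
            out += layer.params
        return out + self.encoder.params + self.decoder.params

    def graph_embeddings(self) -> Tensor:
        f = self.feats
        n = f.node.shape[0]
        h = self.node_embed(Tensor(f.node)).tanh()
        e = self.edge_embed(Tensor(f.edge)).tanh()
        for we, wn in zip(self.edge_upd, self.node_upd):
            msg = we(concat([gather(h, f.src), gather(h, f.dst), e])).tanh()
            agg = scatter_add(msg, f.dst, n)
            h = wn(concat([h, agg])).tanh()
            e = msg
        return h

    def encode_latent(self, x: np.ndarray) -> np.ndarray:
        return self.encoder(Tensor(x)).data

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> Tensor:
        """x: (B·N, in_dim) node feature rows, canonical slab order, batch
        major.  During training multiplicative Gaussian noise at
        ``noise_percent`` is applied to the latent code."""
        n = self.feats.node.shape[0]
        b = x.shape[0] // n
        z = self.encoder(Tensor(x))
        if training and self.cfg.noise_percent > 0:
            eps = rng.standard_normal(z.shape)
            z = z * Tensor(1.0 + self.cfg.noise_percent * eps)
        hv = self.graph_embeddings()
        tiled = gather(hv, np.tile(np.arange(n), b))
        return self.decoder(concat([tiled, z]))

    def state(self):
        return [p.data.copy() for p in self.params]

    def load_state(self, state):
        for p, d in zip(self.params, state):
            p.data = d.copy()


class NaiveAE:
    """Whole-tensor autoencoder: the flattened F tensor through a dense
    bottleneck, no graph conditioning.  Comparison arm only — it cannot
    condition on topology, so its capacity is spent on the full N×m×3
    layout at once."""

    variant = "naive_ae"

    def __init__(self, in_dim: int, cfg: TrainConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = _MLP([in_dim, 128, 128, cfg.latent_dim], rng)
        self.decoder = _MLP([cfg.latent_dim, 128, 128, in_dim], rng)

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def encode_latent(self, x):
        return self.encoder(Tensor(x)).data

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> Tensor:
        z = self.encoder(Tensor(x))
        if training and self.cfg.noise_percent > 0:
            eps = rng.standard_normal(z.shape)
            z = z * Tensor(1.0 + self.cfg.noise_percent * eps)
        return self.decoder(z)

    def state(self):
        return [p.data.copy() for p in self.params]

    def load_state(self, state):
        for p, d in zip(self.params, state):
            p.data = d.copy()


def encode_ensemble(confs: list, ctx: GraphContext, m: int | None = None):
    """Encode every conformer; returns (X, headers) with X of shape
    (n_conf, N, m, 3) and one GIERCM header per conformer."""
    if m is None:
        m = ctx.max_neighborhood_size()
    fs = [encode(c, ctx, m=m) for c in confs]
    x = np.stack([f.features for f in fs])
    return x, fs


def padding_mask(ctx: GraphContext) -> np.ndarray:
    """(N, m·3) mask of valid (non-padding) feature entries per canonical
    slab; identical for every conformer of the molecule."""
    s = ctx.base_order
    m = ctx.max_neighborhood_size()
    mask = np.zeros((ctx.g.n_atoms, m, 3))
    for pos, atom in enumerate(s.order):
        mask[pos, : len(ctx.neighborhood(s, atom))] = 1.0
    return mask.reshape(ctx.g.n_atoms, m * 3)


def _prepare(x, model):
    if model.variant == "graph_ae":
        n_conf, n, m, _ = x.shape
        return x.reshape(n_conf, n, m * 3)
    n_conf = x.shape[0]
    return x.reshape(n_conf, -1)


def _train(model, x, mask_flat, cfg: TrainConfig, is_node_level: bool):
    rng = np.random.default_rng(cfg.seed + 1)
    n_conf = x.shape[0]
    n_val = max(1, int(round(cfg.val_fraction * n_conf)))
    perm = rng.permutation(n_conf)
    val_idx, trn_idx = perm[:n_val], perm[n_val:]

    def batch_input(idx):
        xb = x[idx]
        if is_node_level:
            return xb.reshape(-1, xb.shape[-1])
        return xb

    def batch_mask(idx):
        if is_node_level:
            return np.tile(mask_flat, (len(idx), 1))
        return np.tile(mask_flat.ravel(), (len(idx), 1))

    def eval_loss(idx):
        pred = model.forward(batch_input(idx), training=False)
        return float(masked_mse(pred, batch_input(idx), batch_mask(idx)).data)

    opt = Adam(model.params, lr=cfg.lr)
    best_val = np.inf
    best_state = model.state()
    since_improve = 0
    since_lr_drop = 0
    log = {"train_loss": [], "val_loss": [], "lr": []}
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(trn_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            xb = batch_input(idx)
            pred = model.forward(xb, training=True, rng=rng)
            loss = masked_mse(pred, xb, batch_mask(idx))
            if not np.isfinite(loss.data) or loss.data > 1e10:
                raise RuntimeError(
                    f"training diverged (loss={loss.data}) at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val = eval_loss(val_idx)
        log["train_loss"].append(float(np.mean(losses)))
        log["val_loss"].append(val)
        log["lr"].append(opt.lr)
        if val < best_val - 1e-12:
            best_val = val
            best_state = model.state()
            since_improve = 0
            since_lr_drop = 0
        else:
            since_improve += 1
            since_lr_drop += 1
        if since_lr_drop >= cfg.plateau_patience:
            opt.lr *= 0.5
            since_lr_drop = 0
        if opt.lr < cfg.lr_min or since_improve >= cfg.early_stop:
            break
    model.load_state(best_state)
    log["best_val_loss"] = best_val
    log["val_indices"] = [int(k) for k in val_idx]
    return model, log


def train_graph_ae(x: np.ndarray, ctx: GraphContext, cfg: TrainConfig | None = None):
    """Train the graph-conditioned AE on an encoded ensemble
    (x: n_conf × N × m × 3).  Returns (model, training log)."""
    cfg = cfg or TrainConfig()
    if x.shape[0] < 10:
        raise ValueError("need at least 10 conformers to split 9:1")
    feats = featurize(ctx.g, ctx)
    model = GraphAE(feats, in_dim=x.shape[2] * 3, cfg=cfg)
    mask = padding_mask(ctx)
    return _train(model, _prepare(x, model), mask, cfg, is_node_level=True)


def train_naive_ae(x: np.ndarray, ctx: GraphContext, cfg: TrainConfig | None = None):
    cfg = cfg or TrainConfig()
    if x.shape[0] < 10:
        raise ValueError("need at least 10 conformers to split 9:1")
    model = NaiveAE(in_dim=x.shape[1] * x.shape[2] * 3, cfg=cfg)
    mask = padding_mask(ctx)
    return _train(model, _prepare(x, model), mask, cfg, is_node_level=False)


def reconstruct(model, x_single: np.ndarray) -> np.ndarray:
    """Noise-free forward pass of one conformer's features (N, m, 3)."""
    n, m, _ = x_single.shape
    if model.variant == "graph_ae":
        out = model.forward(x_single.reshape(n, m * 3), training=False)
    else:
        out = model.forward(x_single.reshape(1, -1), training=False)
    return out.data.reshape(n, m, 3)


def reconstruction_errors(model, confs, headers, ctx: GraphContext, eps=None):
    """Mean coordinate and torsion RMSD between conformers and the decodes
    of their model reconstructions."""
    from .bench import kabsch_rmsd, torsion_rmsd
    from .codec import DEFAULT_EPS

    eps = eps or DEFAULT_EPS
    crmsd, trmsd = [], []
    for conf, hdr in zip(confs, headers):
        rec = reconstruct(model, hdr.features)
        f = GIERCM(features=rec, order=hdr.order, m=hdr.m, rcs=hdr.rcs,
                   rc=hdr.rc, fingerprint=hdr.fingerprint)
        dec = decode(f, ctx, eps=eps)
        crmsd.append(kabsch_rmsd(conf, dec))
        trmsd.append(torsion_rmsd(conf, dec, ctx))
    return float(np.mean(crmsd)), float(np.mean(trmsd))


def interpolate(model, ctx: GraphContext, conf_a: Conformer, conf_b: Conformer,
                steps: int = 20):
    """Linear path in latent space between two conformers, decoded at
    ``steps`` equal intervals (inclusive endpoints → steps+1 structures).

    Only z_v is interpolated: the graph embedding h_v is topology-determined
    and identical at both endpoints.  Decoding uses the first endpoint's
    slab order.  Returns a list of (t, Conformer | None); a failed decode
    yields None and the path continues.
    """
    m = ctx.max_neighborhood_size()
    fa = encode(conf_a, ctx, m=m)
    fb = encode(conf_b, ctx, m=m)
    n = ctx.g.n_atoms

    def latent(f):
        if model.variant == "graph_ae":
            return model.encode_latent(f.features.reshape(n, m * 3))
        return model.encode_latent(f.features.reshape(1, -1))

    za, zb = latent(fa), latent(fb)
    out = []
    for t in np.linspace(0.0, 1.0, steps + 1):
        z = (1.0 - t) * za + t * zb
        if model.variant == "graph_ae":
            hv = model.graph_embeddings()
            rec = model.decoder(concat([hv, Tensor(z)])).data.reshape(n, m, 3)
        else:
            rec = model.decoder(Tensor(z)).data.reshape(n, m, 3)
        f = GIERCM(features=rec, order=fa.order, m=m, rcs=fa.rcs, rc=fa.rc,
                   fingerprint=fa.fingerprint)
        try:
            out.append((float(t), decode(f, ctx)))
        except (ValueError, FloatingPointError):
            out.append((float(t), None))
    return out


def torsion_matrix(confs, ctx: GraphContext) -> np.ndarray:
    quads = canonical_torsions(ctx.g, ctx.base_order)
    return np.stack([torsion_values(c, quads) for c in confs])


def cluster_conformers(confs, ctx: GraphContext, eps: float = 30.0,
                       min_samples: int = 5, min_cluster_size: int = 1):
    """DBSCAN in torsion space with the circular (wrapped) Euclidean metric;
    clusters smaller than ``min_cluster_size`` are relabelled as noise (−1)."""
    if len(confs) < 2:
        raise ValueError("need at least 2 conformers")
    t = torsion_matrix(confs, ctx)
    diff = wrap_degrees(t[:, None, :] - t[None, :, :])
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(dist).labels_
    for lab in set(labels) - {-1}:
        if np.sum(labels == lab) < min_cluster_size:
            labels[labels == lab] = -1
    return labels
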