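"""The GIE-RC codec: reversible, SE(3)- and exchange-invariant encoding.

Encoding: every atom i gets a local right-handed frame built from its two
graph-closest neighbors a, b.  The positions of all atoms within three bonds
of i, expressed in that frame and scaled by an attenuation factor derived
from the weighted 2D graph distance, form the local structure feature F_i.
Stacking all F_i in canonical atom order gives the N×m×3 feature tensor
(GIE-RCM).  Because the scale factor depends only on topology, the local
geometry is exactly recoverable from F_i, and every spanning-tree internal
coordinate is observed in several overlapping local structures.  Decoding
averages those redundant estimates (after density-based outlier rejection)
and rebuilds Cartesians through the NeRF scheme — losslessly when the
features are unperturbed, and with strong error cancellation when they are
noisy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .internal import (
    Conformer,
    InternalCoordinateSet,
    build_tree,
    rebuild_cartesian,
    wrap_degrees,
)
from .molgraph import (
    CanonicalOrder,
    MolecularGraph,
    _bond_count_distances,
    canonical_order,
    coulomb_matrix,
    resolve_orbits,
    topo_neighborhood,
    weighted_graph_distances,
)

logger = logging.getLogger(__name__)

DEFAULT_RCS = 5.0
DEFAULT_RC = 6.0
#: density-clustering widths for bond / angle / dihedral consensus
DEFAULT_EPS = (0.1, 20.0, 20.0)

__all__ = [
    "GraphContext",
    "LocalFrame",
    "LocalStructureFeature",
    "GIERCM",
    "ICEstimates",
    "attenuation",
    "build_local_frame",
    "encode_local",
    "encode",
    "local_positions_from_feature",
    "extract_internal_coords",
    "consensus_internal_coords",
    "cluster_1d",
    "circular_mean",
    "decode",
    "ring_closure_report",
]


def attenuation(r2d: float, rcs: float = DEFAULT_RCS, rc: float = DEFAULT_RC):
    """Smooth cutoff S2D(r): 1/r below rcs, cosine-switched to zero at rc."""
    if not 0 < rcs < rc:
        raise ValueError("require 0 < rcs < rc")
    r = np.asarray(r2d, dtype=float)
    if np.any(r <= 0):
        raise ValueError("graph distance must be positive")
    out = np.zeros_like(r)
    near = r < rcs
    mid = (r >= rcs) & (r < rc)
    out[near] = 1.0 / r[near]
    out[mid] = (1.0 / r[mid]) * (
        0.5 * np.cos(np.pi * (r[mid] - rcs) / (rc - rcs)) + 0.5
    )
    return float(out) if np.isscalar(r2d) else out


class GraphContext:
    """Caches the topology-derived quantities the codec reuses per molecule:
    weighted distances, Coulomb matrix, base canonical order, bond-count
    distances and the 3-bond candidate sets."""

    def __init__(self, g: MolecularGraph, rcs: float = DEFAULT_RCS, rc: float = DEFAULT_RC):
        if not 0 < rcs < rc:
            raise ValueError("require 0 < rcs < rc")
        self.g = g
        self.rcs = rcs
        self.rc = rc
        self.r2d = weighted_graph_distances(g)
        self.coulomb = coulomb_matrix(g, self.r2d)
        self.base_order = canonical_order(self.coulomb, g)
        self.hops = _bond_count_distances(g)
        self.fingerprint = g.fingerprint()

    def order_for(self, conf: Conformer) -> CanonicalOrder:
        """Canonical order with automorphism-orbit ties broken geometrically
        (relabeling- and rigid-motion-invariant), so the encoding of any
        relabeled copy of the same conformer is elementwise identical."""
        return resolve_orbits(self.base_order, conf.coords)

    def neighborhood(self, s: CanonicalOrder, i: int) -> list:
        return topo_neighborhood(self.g, self.r2d, s, i, _hops=self.hops)

    def max_neighborhood_size(self) -> int:
        return int(max(np.sum((self.hops[i] <= 3)) - 1 for i in range(self.g.n_atoms)))


@dataclass(frozen=True)
class LocalFrame:
    """Atom-centered right-handed orthonormal frame (rows of ``axes`` are
    the x, y, z unit vectors in lab coordinates)."""

    center: int
    ref_a: int
    ref_b: int
    origin: np.ndarray
    axes: np.ndarray


@dataclass(frozen=True)
class LocalStructureFeature:
    """Attenuated relative coordinates of atom ``center``'s 3-bond
    neighborhood, rows ordered like the topological neighborhood and
    zero-padded to width m."""

    center: int
    neighbor_ids: tuple
    rc: np.ndarray


@dataclass(frozen=True)
class GIERCM:
    """The N×m×3 feature tensor, atom slabs sorted by canonical order."""

    features: np.ndarray
    order: tuple
    m: int
    rcs: float
    rc: float
    fingerprint: str


@dataclass
class ICEstimates:
    """Per internal coordinate: the (value, source center) estimates gathered
    from every local structure containing the coordinate's atom tuple."""

    records: tuple
    bonds: list
    angles: list
    dihedrals: list


def build_local_frame(
    conf: Conformer, ctx: GraphContext, s: CanonicalOrder, i: int,
    neighborhood: list | None = None,
) -> LocalFrame:
    """Frame at atom i: x along i→a, z along (i→a)×(i→b), y completing the
    right-handed set, where a, b are the two graph-closest neighbors (ties by
    canonical rank).  A neighbor collinear with i→a is skipped and the next
    one in topological order promoted."""
    nbh = ctx.neighborhood(s, i) if neighborhood is None else neighborhood
    if len(nbh) < 2:
        raise ValueError(f"atom {i} has fewer than two topological neighbors")
    origin = conf.coords[i]
    a = nbh[0]
    x = conf.coords[a] - origin
    x = x / np.linalg.norm(x)
    for b in nbh[1:]:
        v = conf.coords[b] - origin
        v = v / np.linalg.norm(v)
        z = np.cross(x, v)
        nz = np.linalg.norm(z)
        if nz > 1e-3:
            z = z / nz
            y = np.cross(z, x)
            return LocalFrame(center=i, ref_a=a, ref_b=b, origin=origin,
                              axes=np.array([x, y, z]))
    raise ValueError(f"degenerate local frame: all neighbors of atom {i} collinear")


def encode_local(
    conf: Conformer, ctx: GraphContext, s: CanonicalOrder, i: int, m: int
) -> LocalStructureFeature:
    """F_i rows: C_j = S2D(r_ij)/r_ij · (local coordinates of neighbor j)."""
    nbh = ctx.neighborhood(s, i)
    frame = build_local_frame(conf, ctx, s, i, neighborhood=nbh)
    if len(nbh) > m:
        raise ValueError(
            f"padding width m={m} too small; atom {i} needs {len(nbh)}"
        )
    rows = np.zeros((m, 3))
    for k, j in enumerate(nbh):
        r = float(ctx.r2d.values[i, j])
        scale = attenuation(r, ctx.rcs, ctx.rc) / r
        local = frame.axes @ (conf.coords[j] - frame.origin)
        rows[k] = scale * local
    return LocalStructureFeature(center=i, neighbor_ids=tuple(nbh), rc=rows)


def encode(conf: Conformer, ctx: GraphContext, m: int | None = None) -> GIERCM:
    """Encode a conformer into the GIE-RC tensor (slabs in canonical order)."""
    need = ctx.max_neighborhood_size()
    if m is None:
        m = need
    elif m < need:
        raise ValueError(f"padding width m={m} too small; need at least {need}")
    s = ctx.order_for(conf)
    feats = np.zeros((ctx.g.n_atoms, m, 3))
    for pos, atom in enumerate(s.order):
        feats[pos] = encode_local(conf, ctx, s, atom, m).rc
    return GIERCM(
        features=feats, order=s.order, m=m,
        rcs=ctx.rcs, rc=ctx.rc, fingerprint=ctx.fingerprint,
    )


def local_positions_from_feature(
    f: LocalStructureFeature, ctx: GraphContext, center: int
) -> dict:
    """Invert the attenuation scaling: neighbor positions in the local frame
    (center at the origin).  Neighbors whose attenuation is exactly zero are
    unrecoverable and excluded with a logged warning."""
    pos = {center: np.zeros(3)}
    for k, j in enumerate(f.neighbor_ids):
        r = float(ctx.r2d.values[center, j])
        scale = attenuation(r, ctx.rcs, ctx.rc)
        if scale == 0.0:
            logger.warning(
                "neighbor %d of atom %d beyond rc (r2d=%.2f Å); unrecoverable",
                j, center, r,
            )
            continue
        pos[j] = f.rc[k] * (r / scale)
    return pos


def _local_bond(pos, a, b):
    return float(np.linalg.norm(pos[a] - pos[b]))


def _local_angle(pos, a, b, c):
    u = pos[a] - pos[b]
    v = pos[c] - pos[b]
    cv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cv, -1.0, 1.0))))


def _local_dihedral(pos, a, b, c, d):
    b0 = pos[a] - pos[b]
    b1 = pos[c] - pos[b]
    b2 = pos[d] - pos[c]
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(wrap_degrees(math.degrees(math.atan2(
        np.dot(np.cross(b1, v), w), np.dot(v, w)))))


def extract_internal_coords(
    local_positions: dict, records: tuple
) -> ICEstimates:
    """Gather one estimate of every spanning-tree internal coordinate from
    each local structure that contains the full atom tuple."""
    members = {c: set(pos.keys()) for c, pos in local_positions.items()}
    est = ICEstimates(records=records, bonds=[], angles=[], dihedrals=[])
    for rec in records:
        if len(rec) >= 2:
            est.bonds.append(_collect(rec[:2], members, local_positions, _local_bond))
        if len(rec) >= 3:
            est.angles.append(_collect(rec[:3], members, local_positions, _local_angle))
        if len(rec) == 4:
            est.dihedrals.append(_collect(rec, members, local_positions, _local_dihedral))
    return est


def _collect(tup, members, local_positions, fn):
    out = []
    for c, mem in members.items():
        if all(a in mem for a in tup):
            out.append((fn(local_positions[c], *tup), c))
    if not out:
        raise ValueError(f"internal coordinate {tup} found in no local structure")
    return out


def cluster_1d(values, eps: float, circular: bool = False) -> list:
    """Density clusters of 1-D values: connected components of the graph
    linking points closer than eps (circular distance on [−180, 180) when
    ``circular``).  Equivalent to DBSCAN with min_samples=1.  Returns index
    lists, largest cluster first (ties by smallest member value)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 1:
        return [[0]]
    idx = np.argsort(v, kind="stable")
    sv = v[idx]
    gaps = np.diff(sv)
    cuts = np.flatnonzero(gaps > eps)
    groups = np.split(idx, cuts + 1)
    if circular and len(groups) > 1:
        wrap_gap = (sv[0] + 360.0) - sv[-1]
        if wrap_gap <= eps:
            groups = [np.concatenate([groups[-1], groups[0]])] + groups[1:-1]
    groups = [list(map(int, grp)) for grp in groups]
    groups.sort(key=lambda grp: (-len(grp), min(v[k] for k in grp)))
    return groups


def circular_mean(values_deg) -> float:
    v = np.radians(np.asarray(values_deg, dtype=float))
    return float(wrap_degrees(np.degrees(
        np.arctan2(np.mean(np.sin(v)), np.mean(np.cos(v))))))


def consensus_internal_coords(
    est: ICEstimates, eps: tuple = DEFAULT_EPS
) -> InternalCoordinateSet:
    """Keep the biggest density cluster per coordinate and average it —
    arithmetic mean for bond lengths, circular mean for angles and
    dihedrals."""
    eps_bond, eps_angle, eps_dih = eps

    def consensus(pairs, e, circular):
        vals = [p[0] for p in pairs]
        best = cluster_1d(vals, e, circular=circular)[0]
        kept = [vals[k] for k in best]
        return circular_mean(kept) if circular else float(np.mean(kept))

    bonds = [consensus(p, eps_bond, False) for p in est.bonds]
    angles = [consensus(p, eps_angle, True) for p in est.angles]
    angles = np.clip(np.abs(angles), 1e-3, 180 - 1e-3)
    dihs = [consensus(p, eps_dih, True) for p in est.dihedrals]
    return InternalCoordinateSet(
        records=est.records,
        bond_lengths=np.array(bonds),
        bond_angles=np.array(angles),
        dihedrals=wrap_degrees(np.array(dihs)),
    )


def decode(
    f: GIERCM, ctx: GraphContext, eps: tuple = DEFAULT_EPS
) -> Conformer:
    """Decode a feature tensor: invert the local features, pool redundant
    internal-coordinate estimates, take the consensus, rebuild Cartesians."""
    if f.fingerprint != ctx.fingerprint:
        raise ValueError("feature tensor was produced for a different molecule")
    s = CanonicalOrder(order=f.order, colors=ctx.base_order.colors)
    local_positions = {}
    for pos, atom in enumerate(s.order):
        nbh = ctx.neighborhood(s, atom)
        feat = LocalStructureFeature(
            center=atom, neighbor_ids=tuple(nbh), rc=f.features[pos]
        )
        local_positions[atom] = local_positions_from_feature(feat, ctx, atom)
    records = build_tree(ctx.g, s)
    est = extract_internal_coords(local_positions, records)
    ics = consensus_internal_coords(est, eps=eps)
    return rebuild_cartesian(ics, ctx.g)


def ring_closure_report(conf: Conformer, ctx: GraphContext, s: CanonicalOrder) -> dict:
    """Deviation of every non-tree (ring-closure) bond length from its
    standard value, Å.  Diagnostic only; closures are not repaired."""
    tree_edges = set()
    for rec in build_tree(ctx.g, s):
        if len(rec) >= 2:
            tree_edges.add(tuple(sorted(rec[:2])))
    report = {}
    for i, j, order in ctx.g.bonds:
        if (i, j) in tree_edges:
            continue
        actual = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
        from .bondtable import standard_bond_length

        ref = standard_bond_length(
            ctx.g.atomic_numbers[i], ctx.g.atomic_numbers[j], order
        )
        report[(i, j)] = actual - ref
    return report
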