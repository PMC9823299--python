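"""Spanning-tree internal coordinates and Cartesian reconstruction.

A conformation of an N-atom connected molecule is described by 3N−6 internal
coordinates on a spanning tree of the bond graph: one bond length per placed
atom, one bond angle from the third atom on, one dihedral from the fourth.
The tree is built by BFS from the canonical root with children visited in
canonical order, so the construction order is reproducible for a given
molecule.  Cartesian rebuilding follows the natural extension reference
frame (NeRF) scheme: each atom is placed sequentially against its three
reference atoms.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .molgraph import CanonicalOrder, MolecularGraph

__all__ = [
    "Conformer",
    "InternalCoordinateSet",
    "bond_length",
    "bond_angle",
    "dihedral_angle",
    "wrap_degrees",
    "build_tree",
    "to_internal",
    "rebuild_cartesian",
    "canonical_torsions",
    "torsion_values",
]


@dataclass
class Conformer:
    """N×3 Cartesian coordinates (Å) bound to a molecular graph."""

    coords: np.ndarray
    graph: MolecularGraph

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.graph.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.graph.n_atoms} atoms"
            )
        for i, j, _ in self.graph.bonds:
            if np.linalg.norm(self.coords[i] - self.coords[j]) <= 0.1:
                raise ValueError(f"bonded atoms {i},{j} nearly coincide")


@dataclass
class InternalCoordinateSet:
    """Z-matrix on a spanning tree.

    ``records[k]`` is the placement record of the k-th atom in construction
    order: ``(atom,)``, ``(atom, parent)``, ``(atom, parent, angle_ref)`` or
    ``(atom, parent, angle_ref, dihedral_ref)``.  Bond lengths are in Å,
    angles in (0, 180)°, dihedrals wrapped to [−180, 180)°.
    """

    records: tuple
    bond_lengths: np.ndarray
    bond_angles: np.ndarray
    dihedrals: np.ndarray

    def __post_init__(self):
        self.bond_lengths = np.asarray(self.bond_lengths, dtype=float)
        self.bond_angles = np.asarray(self.bond_angles, dtype=float)
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        n = len(self.records)
        if (
            len(self.bond_lengths) != n - 1
            or len(self.bond_angles) != n - 2
            or len(self.dihedrals) != n - 3
        ):
            raise ValueError("internal coordinate arrays inconsistent with records")
        placed = set()
        for rec in self.records:
            if any(ref in (rec[0],) or ref not in placed for ref in rec[1:]):
                raise ValueError(f"record {rec} references an unplaced atom")
            placed.add(rec[0])

    def flat(self) -> np.ndarray:
        return np.concatenate([self.bond_lengths, self.bond_angles, self.dihedrals])

    def with_values(self, flat: np.ndarray) -> "InternalCoordinateSet":
        n = len(self.records)
        b, a, d = flat[: n - 1], flat[n - 1 : 2 * n - 3], flat[2 * n - 3 :]
        return InternalCoordinateSet(
            records=self.records,
            bond_lengths=b,
            bond_angles=np.clip(a, 1e-3, 180 - 1e-3),
            dihedrals=wrap_degrees(d),
        )


def wrap_degrees(x):
    """Wrap angle(s) to [−180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def bond_length(coords, i, j) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def bond_angle(coords, i, j, k) -> float:
    """Angle i–j–k at vertex j, degrees."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_angle(coords, a, b, c, d) -> float:
    """Signed torsion a–b–c–d, degrees in [−180, 180)."""
    b0 = coords[a] - coords[b]
    b1 = coords[c] - coords[b]
    b2 = coords[d] - coords[c]
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(wrap_degrees(np.degrees(np.arctan2(y, x))))


def build_tree(g: MolecularGraph, s: CanonicalOrder) -> tuple:
    """BFS spanning-tree placement records from the canonical root.

    Children are visited in canonical-rank order.  Angle references are the
    earliest-placed neighbor of the parent; dihedral references extend the
    bonded chain where possible and fall back to an improper reference (a
    second placed neighbor of the parent) near branch points, keeping every
    reference tuple within three bonds of its atom.
    """
    root = s.order[0]
    parent = {root: None}
    placed_at = {root: 0}
    order = [root]
    queue = deque([root])
    nbrs = g.neighbors
    while queue:
        u = queue.popleft()
        for v in sorted(nbrs[u], key=lambda x: s.rank[x]):
            if v not in parent:
                parent[v] = u
                placed_at[v] = len(order)
                order.append(v)
                queue.append(v)

    records = []
    for k, a in enumerate(order):
        def earliest(cands, exclude, _k=k):
            cands = [c for c in cands if placed_at[c] < _k and c not in exclude]
            return min(cands, key=lambda c: placed_at[c]) if cands else None

        if k == 0:
            records.append((a,))
            continue
        p = parent[a]
        if k == 1:
            records.append((a, p))
            continue
        q = earliest(nbrs[p], {a})
        if q is None:  # parent's only placed neighbor is a itself
            q = earliest(order[:k], {a, p})
        if k == 2:
            records.append((a, p, q))
            continue
        r = earliest(nbrs[q], {a, p})
        if r is None:
            r = earliest(nbrs[p], {a, q})
        if r is None:
            r = earliest(order[:k], {a, p, q})
        records.append((a, p, q, r))
    return tuple(records)


def to_internal(conf: Conformer, records: tuple) -> InternalCoordinateSet:
    """Measure the spanning-tree internal coordinates from Cartesians."""
    c = conf.coords
    bonds, angles, dihedrals = [], [], []
    for rec in records:
        if len(rec) >= 2:
            bonds.append(bond_length(c, rec[0], rec[1]))
        if len(rec) >= 3:
            angles.append(bond_angle(c, rec[0], rec[1], rec[2]))
        if len(rec) == 4:
            dihedrals.append(dihedral_angle(c, *rec))
    return InternalCoordinateSet(
        records=records,
        bond_lengths=np.array(bonds),
        bond_angles=np.array(angles),
        dihedrals=np.array(dihedrals),
    )


def _place(p, q, r, d, theta, phi):
    """NeRF placement: atom at distance d from p, angle θ=∠(a,p,q),
    torsion φ=dihedral(a,p,q,r)."""
    u = q - p
    u = u / np.linalg.norm(u)
    w = r - q
    n = np.cross(u, w)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("degenerate placement: reference atoms collinear")
    n = n / nn
    m = np.cross(n, u)
    th = np.radians(theta)
    ph = np.radians(phi)
    if not 0.0 < theta < 180.0:
        raise ValueError(f"degenerate placement: angle {theta}")
    # components in the (u, m, n) frame; signs fixed so that
    # dihedral_angle(a, p, q, r) == phi
    return p + d * (np.cos(th) * u + np.sin(th) * (np.cos(ph) * m - np.sin(ph) * n))


def rebuild_cartesian(ics: InternalCoordinateSet, g: MolecularGraph) -> Conformer:
    """Sequential NeRF reconstruction: first atom at the origin, second on
    +x, third in the xy-plane, the rest by (bond, angle, dihedral)."""
    n = len(ics.records)
    coords = np.zeros((n, 3))
    pos = {}
    for k, rec in enumerate(ics.records):
        a = rec[0]
        if k == 0:
            pos[a] = np.zeros(3)
        elif k == 1:
            pos[a] = pos[rec[1]] + np.array([ics.bond_lengths[0], 0.0, 0.0])
        elif k == 2:
            p, q = pos[rec[1]], pos[rec[2]]
            d, theta = ics.bond_lengths[1], np.radians(ics.bond_angles[0])
            u = q - p
            u = u / np.linalg.norm(u)
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-10:
                perp = np.array([0.0, 1.0, 0.0])
            perp = perp / np.linalg.norm(perp)
            pos[a] = p + d * (np.cos(theta) * u + np.sin(theta) * perp)
        else:
            p, q, r = (pos[x] for x in rec[1:])
            pos[a] = _place(
                p, q, r,
                ics.bond_lengths[k - 1],
                ics.bond_angles[k - 2],
                ics.dihedrals[k - 3],
            )
    for a, xyz in pos.items():
        coords[a] = xyz
    return Conformer(coords=coords, graph=g)


def canonical_torsions(g: MolecularGraph, s: CanonicalOrder) -> tuple:
    """One canonical dihedral per non-terminal bond: the lowest-rank flanking
    atom on each side.  Raises if the molecule has no torsions."""
    nbrs = g.neighbors
    quads = []
    for i, j, _ in g.bonds:
        if len(nbrs[i]) < 2 or len(nbrs[j]) < 2:
            continue
        a = min((x for x in nbrs[i] if x != j), key=lambda x: s.rank[x])
        d = min((x for x in nbrs[j] if x != i), key=lambda x: s.rank[x])
        quads.append((a, i, j, d))
    if not quads:
        raise ValueError("no torsions in molecule")
    return tuple(quads)


def torsion_values(conf: Conformer, quads: tuple) -> np.ndarray:
    return np.array([dihedral_angle(conf.coords, *q) for q in quads])
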