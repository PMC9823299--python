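"""Molecular graph, weighted 2D distances, Coulomb matrix, canonical order.

Everything in the encoding that must be permutation invariant is derived
here, from topology alone: the weighted graph distance matrix (shortest bond
paths under standard bond lengths), the Coulomb matrix built on those
distances, and the canonical atom order used to serialise per-atom features.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .bondtable import TABLE_VERSION, standard_bond_length

__all__ = [
    "MolecularGraph",
    "WeightedDistanceMatrix",
    "CoulombMatrix",
    "CanonicalOrder",
    "weighted_graph_distances",
    "coulomb_matrix",
    "canonical_order",
    "topo_neighborhood",
    "resolve_orbits",
]


@dataclass(frozen=True)
class MolecularGraph:
    """2D molecular topology: elements, charges, tags and the bond list.

    ``bonds`` holds ``(i, j, order)`` with ``i < j``; order 1.5 denotes an
    aromatic bond.  The graph must be connected, free of self-bonds and
    duplicates, and contain at least four atoms.
    """

    atomic_numbers: tuple
    bonds: tuple
    formal_charges: tuple = None
    chirality_tags: tuple = None
    hybridizations: tuple = None

    def __post_init__(self):
        n = len(self.atomic_numbers)
        object.__setattr__(self, "atomic_numbers", tuple(int(z) for z in self.atomic_numbers))
        if self.formal_charges is None:
            object.__setattr__(self, "formal_charges", (0,) * n)
        else:
            object.__setattr__(self, "formal_charges", tuple(int(c) for c in self.formal_charges))
        if self.chirality_tags is None:
            object.__setattr__(self, "chirality_tags", ("none",) * n)
        if self.hybridizations is None:
            object.__setattr__(self, "hybridizations", self._infer_hybridizations())
        if n < 4:
            raise ValueError(f"need at least 4 atoms, got {n}")
        norm = []
        seen = set()
        for i, j, order in self.bonds:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add((i, j))
            norm.append((i, j, float(order)))
        object.__setattr__(self, "bonds", tuple(norm))
        ncomp, labels = connected_components(self.adjacency_sparse(), directed=False)
        if ncomp != 1:
            comps = [np.flatnonzero(labels == c).tolist() for c in range(ncomp)]
            raise ValueError(f"graph is disconnected; components: {comps}")

    def _infer_hybridizations(self):
        # crude fallback from maximum incident bond order; real inputs carry
        # explicit tags from the SDF reader
        maxo = [1.0] * len(self.atomic_numbers)
        for i, j, o in self.bonds:
            maxo[i] = max(maxo[i], float(o))
            maxo[j] = max(maxo[j], float(o))
        table = {1.0: "sp3", 1.5: "sp2", 2.0: "sp2", 3.0: "sp"}
        return tuple(
            "s" if z == 1 else table.get(o, "sp3")
            for z, o in zip(self.atomic_numbers, maxo)
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def neighbors(self):
        nbrs = [[] for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [sorted(x) for x in nbrs]

    @property
    def degrees(self):
        return tuple(len(nb) for nb in self.neighbors)

    def bond_order(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        for a, b, o in self.bonds:
            if (a, b) == (i, j):
                return o
        raise KeyError(f"no bond ({i},{j})")

    def adjacency_sparse(self, weights=None) -> csr_matrix:
        n = self.n_atoms
        rows, cols, data = [], [], []
        for k, (i, j, _) in enumerate(self.bonds):
            w = 1.0 if weights is None else weights[k]
            rows += [i, j]
            cols += [j, i]
            data += [w, w]
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def fingerprint(self) -> str:
        """Hash of elements, charges, bonds and bond-table version.

        Stable across sessions; used to refuse decoding a feature tensor
        against the wrong molecule.
        """
        payload = repr((self.atomic_numbers, self.formal_charges, self.bonds, TABLE_VERSION))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class WeightedDistanceMatrix:
    """Symmetric matrix of weighted graph distances r^2D (Å), zero diagonal."""

    values: np.ndarray


@dataclass(frozen=True)
class CoulombMatrix:
    """Coulomb matrix on the weighted graph metric: 0.5 Z^2.4 diagonal."""

    values: np.ndarray


@dataclass(frozen=True)
class CanonicalOrder:
    """Canonical atom order S.

    ``order[k]`` is the atom at canonical position k; ``rank`` is its inverse.
    ``colors`` are the refined equivalence classes (equal color ⇔ atoms are
    indistinguishable from topology alone, i.e. an automorphism orbit as far
    as the refinement can tell).
    """

    order: tuple
    rank: tuple = field(init=False)
    colors: tuple = ()

    def __post_init__(self):
        n = len(self.order)
        if sorted(self.order) != list(range(n)):
            raise ValueError("order is not a permutation")
        rank = [0] * n
        for pos, atom in enumerate(self.order):
            rank[atom] = pos
        object.__setattr__(self, "rank", tuple(rank))


def weighted_graph_distances(g: MolecularGraph) -> WeightedDistanceMatrix:
    """All-pairs shortest bond-path lengths, each bond weighted by its
    standard equilibrium length (Dijkstra on the weighted adjacency)."""
    weights = [
        standard_bond_length(g.atomic_numbers[i], g.atomic_numbers[j], o)
        for i, j, o in g.bonds
    ]
    adj = g.adjacency_sparse(weights)
    d = dijkstra(adj, directed=False)
    if not np.all(np.isfinite(d)):
        raise ValueError("graph is disconnected")
    return WeightedDistanceMatrix(values=d)


def coulomb_matrix(g: MolecularGraph, r2d: WeightedDistanceMatrix) -> CoulombMatrix:
    """M_ii = 0.5 Z_i^2.4; M_ij = Z_i Z_j / r_ij^2D."""
    z = np.asarray(g.atomic_numbers, dtype=float)
    if r2d.values.shape != (g.n_atoms, g.n_atoms):
        raise ValueError("distance matrix shape mismatch")
    with np.errstate(divide="ignore"):
        m = np.outer(z, z) / r2d.values
    np.fill_diagonal(m, 0.5 * z**2.4)
    return CoulombMatrix(values=m)


def _bond_count_distances(g: MolecularGraph) -> np.ndarray:
    adj = g.adjacency_sparse()
    return dijkstra(adj, directed=False, unweighted=True)


def canonical_order(m: CoulombMatrix, g: MolecularGraph) -> CanonicalOrder:
    """Derive the canonical atom order S from the Coulomb matrix.

    Atoms are ranked by descending row norm of M, with ties refined by
    (atomic number desc, degree desc, sorted neighbor row norms) and then by
    iterated neighborhood color refinement until stable.  The result is
    invariant under relabeling of the input atoms; atoms left tied after
    refinement are topologically equivalent (automorphism orbit) and fall
    back to input-index order.
    """
    n = g.n_atoms
    row = np.round(np.linalg.norm(m.values, axis=1), 9)
    degs = g.degrees
    nbrs = g.neighbors
    keys = [
        (
            -row[i],
            -g.atomic_numbers[i],
            -degs[i],
            tuple(sorted(row[j] for j in nbrs[i])),
        )
        for i in range(n)
    ]
    colors = _compress(keys)
    while True:
        keys = [(colors[i], tuple(sorted(colors[j] for j in nbrs[i]))) for i in range(n)]
        new = _compress(keys)
        if len(set(new)) == len(set(colors)):
            colors = new
            break
        colors = new
    order = tuple(sorted(range(n), key=lambda i: (colors[i], i)))
    return CanonicalOrder(order=order, colors=tuple(colors))


def _compress(keys):
    """Map sortable keys to dense integer colors (0 = first in sort order)."""
    uniq = sorted(set(keys))
    lut = {k: c for c, k in enumerate(uniq)}
    return [lut[k] for k in keys]


def resolve_orbits(s: CanonicalOrder, coords: np.ndarray) -> CanonicalOrder:
    """Break residual automorphism-orbit ties with a geometric invariant.

    Atoms sharing a refinement color are reordered by the lexicographic sorted
    profile of their Euclidean distances to every other atom — a key that is
    invariant to relabeling and to rigid motion (including reflection), so
    the resulting order makes the full encoding exchange invariant even for
    molecules with symmetric groups (methyl hydrogens etc.).
    """
    n = len(s.order)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    prof = np.sort(np.round(d, 6), axis=1)
    order = sorted(
        range(n),
        key=lambda i: (s.colors[i], tuple(prof[i]), i),
    )
    return CanonicalOrder(order=tuple(order), colors=s.colors)


def topo_neighborhood(
    g: MolecularGraph,
    r2d: WeightedDistanceMatrix,
    s: CanonicalOrder,
    i: int,
    _hops: np.ndarray | None = None,
) -> list:
    """Atoms within three bonds of ``i``, sorted by r^2D then by S rank."""
    if not (0 <= i < g.n_atoms):
        raise IndexError(f"atom index {i} out of range")
    hops = _bond_count_distances(g) if _hops is None else _hops
    cand = [j for j in range(g.n_atoms) if j != i and hops[i, j] <= 3]
    cand.sort(key=lambda j: (round(float(r2d.values[i, j]), 9), s.rank[j]))
    return cand
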