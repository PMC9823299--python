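"""Synthetic molecular graphs and conformer ensembles.

Stands in for MD-derived multi-conformer sets: templates (chains, branched
skeletons, ring-plus-tail scaffolds, peptide-like backbones) are built with
ideal bond lengths and angles, and ensembles are drawn by sampling selected
torsions from user-specified circular mixtures plus small Gaussian jitter on
bonds and angles.  Sampling is purely geometric (torsion-space mixtures, not
Boltzmann weights); the multi-modal torsion structure is the feature of real
ensembles that the generator reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .bondtable import standard_bond_length
from .codec import circular_mean, cluster_1d
from .internal import (
    Conformer,
    build_tree,
    canonical_torsions,
    dihedral_angle,
    rebuild_cartesian,
    to_internal,
    wrap_degrees,
)
from .molgraph import MolecularGraph, canonical_order, coulomb_matrix, weighted_graph_distances

__all__ = [
    "TemplateSpec",
    "EnsembleSpec",
    "make_template",
    "sample_ensemble",
    "exclude_transition_region",
    "rotatable_bonds",
    "key_rotatable_bond",
    "default_ensemble_spec",
]

_VALENCE = {1: 1, 6: 4, 7: 3, 8: 2, 15: 3, 16: 2}


@dataclass(frozen=True)
class TemplateSpec:
    """Which skeleton to build: kind ∈ {chain, branched, ring_plus_tail,
    peptide_like}; n_heavy heavy atoms (peptide_like: total atom target)."""

    kind: str
    n_heavy: int
    include_h: bool = True
    seed: int = 0


@dataclass(frozen=True)
class EnsembleSpec:
    """Per-bond torsion mixtures plus bond/angle jitter.

    ``torsion_modes`` maps a rotatable bond (i, j) to a list of
    (mean °, std °, weight) components; weights must sum to 1.
    """

    n_conformers: int
    torsion_modes: dict
    bond_jitter: float = 0.005
    angle_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for bond, modes in self.torsion_modes.items():
            w = sum(m[2] for m in modes)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"weights for bond {bond} sum to {w}, not 1")
            if any(m[1] < 0 for m in modes):
                raise ValueError("mode std must be >= 0")


def _fill_hydrogens(z, bonds):
    """Append H atoms until every heavy atom reaches its valence."""
    used = [0.0] * len(z)
    for i, j, o in bonds:
        used[i] += o
        used[j] += o
    nh = len(z)
    for i, zi in enumerate(list(z)):
        free = _VALENCE.get(zi, 4) - used[i]
        for _ in range(int(round(max(0.0, free)))):
            z.append(1)
            bonds.append((i, nh, 1))
            nh += 1
    return z, bonds


def _chain_graph(n_heavy, include_h, rng):
    z = [6] * n_heavy
    # sprinkle heteroatoms on interior positions for an asymmetric skeleton
    for i in range(1, n_heavy - 1, 3):
        if rng.random() < 0.5:
            z[i] = int(rng.choice([7, 8]))
    bonds = [(i, i + 1, 1) for i in range(n_heavy - 1)]
    if include_h:
        z, bonds = _fill_hydrogens(z, bonds)
    return MolecularGraph(atomic_numbers=tuple(z), bonds=tuple(bonds)), list(range(n_heavy))


def _branched_graph(n_heavy, include_h, rng):
    n_back = max(4, (2 * n_heavy) // 3)
    n_branch = n_heavy - n_back
    z = [6] * n_back
    bonds = [(i, i + 1, 1) for i in range(n_back - 1)]
    free = {i: 2 for i in range(1, n_back - 1)}
    for _ in range(n_branch):
        sites = sorted(i for i, f in free.items() if f > 0)
        site = int(sites[int(rng.integers(len(sites)))])
        free[site] -= 1
        za = int(rng.choice([6, 6, 8]))
        z.append(za)
        bonds.append((site, len(z) - 1, 1))
    if include_h:
        z, bonds = _fill_hydrogens(z, bonds)
    return MolecularGraph(atomic_numbers=tuple(z), bonds=tuple(bonds)), list(range(n_back))


def _ring_tail_graph(n_heavy, include_h, rng):
    if n_heavy < 7:
        raise ValueError("ring_plus_tail needs n_heavy >= 7")
    z = [6] * n_heavy
    bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    bonds = [(min(a, b), max(a, b), o) for a, b, o in bonds]
    bonds.append((0, 6, 1))
    for i in range(6, n_heavy - 1):
        bonds.append((i, i + 1, 1))
    if include_h:
        z, bonds = _fill_hydrogens(z, bonds)
    return MolecularGraph(atomic_numbers=tuple(z), bonds=tuple(bonds)), None


def _peptide_graph(n_atoms_total, include_h):
    """Glycine-like backbone (N–Cα–C(=O))×r with NH2 / COOH termini; with
    hydrogens each residue contributes 7 atoms and the termini 3 more, so
    r = (n_total − 3) / 7."""
    if include_h:
        r = max(1, round((n_atoms_total - 3) / 7))
    else:
        r = max(1, round((n_atoms_total - 1) / 4))
    z, bonds = [], []
    prev_c = None
    last_c = None
    for _ in range(r):
        n = len(z)
        z += [7, 6, 6, 8]          # N, CA, C, O
        bonds += [(n, n + 1, 1), (n + 1, n + 2, 1), (n + 2, n + 3, 2)]
        if prev_c is not None:
            bonds.append((prev_c, n, 1))
        prev_c = n + 2
        last_c = n + 2
    oxt = len(z)
    z.append(8)                    # C-terminal hydroxyl oxygen
    bonds.append((last_c, oxt, 1))
    backbone = [x for k in range(r) for x in (4 * k, 4 * k + 1, 4 * k + 2)] + [oxt]
    if include_h:
        z, bonds = _fill_hydrogens(z, bonds)
    return MolecularGraph(atomic_numbers=tuple(z), bonds=tuple(bonds)), backbone


def _ideal_angle(g, center):
    heavy_deg = len(g.neighbors[center])
    if heavy_deg >= 4:
        return 109.471
    if heavy_deg == 3:
        return 120.0 if g.hybridizations[center] == "sp2" else 109.471
    return 109.471 if g.hybridizations[center] != "sp2" else 120.0


def _reference_conformer(g: MolecularGraph, backbone=None) -> Conformer:
    """Ideal-geometry reference: table bond lengths, tetrahedral/trigonal
    angles, staggered dihedrals.  Planar aromatic rings and all-trans
    (extended) heavy-atom backbones are seeded explicitly, so chain-like
    templates start from the extended conformation real ensembles fluctuate
    around rather than an arbitrary curl."""
    s = canonical_order(coulomb_matrix(g, weighted_graph_distances(g)), g)
    records = build_tree(g, s)
    ring_atoms = _aromatic_ring(g)
    seeds = {}
    if ring_atoms:
        L = standard_bond_length(6, 6, 1.5)
        rad = L / (2 * np.sin(np.pi / 6))
        for k, a in enumerate(ring_atoms):
            ang = 2 * np.pi * k / 6
            seeds[a] = np.array([rad * np.cos(ang), rad * np.sin(ang), 0.0])
    elif backbone is not None:
        seeds = _backbone_seeds(g, backbone)
    coords = _grow(g, records, seeds)
    return Conformer(coords=coords, graph=g)


def _backbone_seeds(g, atoms):
    """Walk the backbone with ideal bonds/angles and 180° torsions."""
    from .internal import _place

    coords = {}
    for k, a in enumerate(atoms):
        if k == 0:
            coords[a] = np.zeros(3)
            continue
        p = atoms[k - 1]
        d = standard_bond_length(g.atomic_numbers[a], g.atomic_numbers[p],
                                 g.bond_order(a, p))
        if k == 1:
            coords[a] = coords[p] + np.array([d, 0.0, 0.0])
            continue
        q = atoms[k - 2]
        th = np.radians(_ideal_angle(g, p))
        if k == 2:
            u = coords[q] - coords[p]
            u = u / np.linalg.norm(u)
            coords[a] = coords[p] + d * (np.cos(th) * u
                                         + np.sin(th) * np.array([0.0, 1.0, 0.0]))
            continue
        coords[a] = _place(coords[p], coords[q], coords[atoms[k - 3]],
                           d, _ideal_angle(g, p), 180.0)
    return coords


def _aromatic_ring(g):
    """Atoms of the single 6-ring of aromatic bonds, in ring order, if any."""
    arom = [(i, j) for i, j, o in g.bonds if o == 1.5]
    if not arom:
        return None
    nbr = {}
    for i, j in arom:
        nbr.setdefault(i, []).append(j)
        nbr.setdefault(j, []).append(i)
    start = min(nbr)
    ring = [start]
    prev = None
    while len(ring) < len(nbr):
        nxt = [x for x in nbr[ring[-1]] if x != prev]
        prev = ring[-1]
        ring.append(nxt[0])
    return ring


def _grow(g, records, seeds):
    """Place atoms by BFS outward from the seeded coordinates, choosing the
    earliest-placed graph references for angle and torsion."""
    from collections import deque

    from .internal import _place

    n = g.n_atoms
    coords = np.full((n, 3), np.nan)
    when = {}
    if not seeds:
        seeds = {records[0][0]: np.zeros(3)}
    for k, a in enumerate(sorted(seeds)):
        coords[a] = seeds[a]
        when[a] = k
    nbrs = g.neighbors
    queue = deque(sorted(seeds, key=when.get))
    while queue:
        p = queue.popleft()
        for a in sorted(nbrs[p]):
            if a in when:
                continue
            d = standard_bond_length(g.atomic_numbers[a], g.atomic_numbers[p],
                                     g.bond_order(a, p))
            theta = _ideal_angle(g, p)
            q = _earliest_placed(nbrs[p], when, {a})
            if q is None:
                coords[a] = coords[p] + np.array([d, 0.0, 0.0])
            else:
                r = _earliest_placed(nbrs[q], when, {a, p})
                if r is None:
                    r = _earliest_placed(nbrs[p], when, {a, q})
                if r is None:
                    th = np.radians(theta)
                    u = coords[q] - coords[p]
                    u = u / np.linalg.norm(u)
                    perp = np.array([-u[1], u[0], 0.0])
                    if np.linalg.norm(perp) < 1e-8:
                        perp = np.array([0.0, 1.0, 0.0])
                    perp /= np.linalg.norm(perp)
                    coords[a] = coords[p] + d * (np.cos(th) * u + np.sin(th) * perp)
                else:
                    phi = _pick_dihedral(g, coords, when, a, p, q, r)
                    coords[a] = _place(coords[p], coords[q], coords[r], d, theta, phi)
            when[a] = len(when)
            queue.append(a)
    return coords


def _earliest_placed(cands, when, exclude):
    cands = [c for c in cands if c in when and c not in exclude]
    return min(cands, key=when.get) if cands else None


def _pick_dihedral(g, coords, placed, a, p, q, r):
    """Stagger substituents: choose the candidate torsion farthest from the
    torsions already occupied around the p–q axis."""
    occupied = []
    for x in g.neighbors[p]:
        if x in placed and x not in (q, a):
            pts = {0: coords[x], 1: coords[p], 2: coords[q], 3: coords[r]}
            occupied.append(dihedral_angle(pts, 0, 1, 2, 3))
    candidates = [180.0, 60.0, -60.0, 120.0, -120.0, 0.0]
    if not occupied:
        return candidates[0]

    def separation(c):
        return min(
            180 - abs(abs(c - o) % 360 - 180) for o in occupied
        )

    return max(candidates, key=separation)


def make_template(spec: TemplateSpec):
    """Deterministic graph + ideal reference conformer for the template."""
    if spec.n_heavy < 4:
        raise ValueError("need n_heavy >= 4")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "chain":
        g, backbone = _chain_graph(spec.n_heavy, spec.include_h, rng)
    elif spec.kind == "branched":
        g, backbone = _branched_graph(spec.n_heavy, spec.include_h, rng)
    elif spec.kind == "ring_plus_tail":
        g, backbone = _ring_tail_graph(spec.n_heavy, spec.include_h, rng)
    elif spec.kind == "peptide_like":
        g, backbone = _peptide_graph(spec.n_heavy, spec.include_h)
    else:
        raise ValueError(f"unknown template kind {spec.kind!r}")
    return g, _reference_conformer(g, backbone=backbone)


def rotatable_bonds(g: MolecularGraph) -> list:
    """Single, acyclic (bridge) bonds between two non-terminal atoms."""
    deg = g.degrees
    out = []
    for i, j, o in g.bonds:
        if o != 1 or deg[i] < 2 or deg[j] < 2:
            continue
        if _is_bridge(g, (i, j)):
            out.append((i, j))
    return out


def _is_bridge(g, edge):
    n = g.n_atoms
    rows, cols = [], []
    for i, j, _ in g.bonds:
        if (i, j) == edge:
            continue
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp > 1


def key_rotatable_bond(g: MolecularGraph):
    """The most central rotatable bond: the one whose removal splits the
    molecule most evenly (deterministic ties by index)."""
    rots = rotatable_bonds(g)
    if not rots:
        raise ValueError("molecule has no rotatable bonds")

    def balance(edge):
        n = g.n_atoms
        rows, cols = [], []
        for i, j, _ in g.bonds:
            if (i, j) == edge:
                continue
            rows += [i, j]
            cols += [j, i]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels)
        return int(sizes.min())

    return max(rots, key=lambda e: (balance(e), -e[0], -e[1]))


def default_ensemble_spec(
    g: MolecularGraph,
    ref: Conformer,
    n_conformers: int,
    seed: int = 0,
    bimodal_bond=None,
    mode_std: float = 10.0,
) -> EnsembleSpec:
    """Study-condition defaults: the key (most central) rotatable bond gets a
    balanced bimodal mixture at 60° and 180° (std 10°); every other rotatable
    bond fluctuates unimodally about its reference value with std 10°."""
    if bimodal_bond is None:
        bimodal_bond = key_rotatable_bond(g)
    s = canonical_order(coulomb_matrix(g, weighted_graph_distances(g)), g)
    records = build_tree(g, s)
    ics = to_internal(ref, records)
    primary = _primary_dihedral_by_bond(records)
    modes = {}
    for bond in rotatable_bonds(g):
        if bond == tuple(sorted(bimodal_bond)):
            modes[bond] = [(180.0, mode_std, 0.5), (60.0, mode_std, 0.5)]
        elif bond in primary:
            ref_val = float(ics.dihedrals[primary[bond]])
            modes[bond] = [(ref_val, mode_std, 1.0)]
    return EnsembleSpec(n_conformers=n_conformers, torsion_modes=modes, seed=seed)


def _primary_dihedral_by_bond(records):
    """First tree-dihedral index whose central bond is (p, q), per bond."""
    out = {}
    di = 0
    for rec in records:
        if len(rec) == 4:
            bond = tuple(sorted((rec[1], rec[2])))
            out.setdefault(bond, di)
            di += 1
    return out


def sample_ensemble(g: MolecularGraph, ref: Conformer, spec: EnsembleSpec) -> list:
    """Draw conformers: per flagged bond, sample a torsion from its mixture
    and rotate the whole group of tree dihedrals sharing that central bond by
    the same offset (substituents ride along); jitter bonds and angles; then
    rebuild Cartesians through the NeRF scheme."""
    rng = np.random.default_rng(spec.seed)
    s = canonical_order(coulomb_matrix(g, weighted_graph_distances(g)), g)
    records = build_tree(g, s)
    ics0 = to_internal(ref, records)
    groups = {}
    di = 0
    for rec in records:
        if len(rec) == 4:
            groups.setdefault(tuple(sorted((rec[1], rec[2]))), []).append(di)
            di += 1
    rot = set(map(tuple, (tuple(sorted(b)) for b in spec.torsion_modes)))
    for bond in rot:
        if bond not in groups:
            raise ValueError(f"bond {bond} controls no tree dihedral")
    confs = []
    for _ in range(spec.n_conformers):
        b = ics0.bond_lengths + rng.normal(0, spec.bond_jitter, ics0.bond_lengths.shape) \
            if spec.bond_jitter > 0 else ics0.bond_lengths.copy()
        a = ics0.bond_angles + rng.normal(0, spec.angle_jitter, ics0.bond_angles.shape) \
            if spec.angle_jitter > 0 else ics0.bond_angles.copy()
        a = np.clip(a, 5.0, 175.0)
        d = ics0.dihedrals.copy()
        for bond, modes in spec.torsion_modes.items():
            bond = tuple(sorted(bond))
            weights = [m[2] for m in modes]
            k = rng.choice(len(modes), p=weights)
            mean, std, _ = modes[k]
            tau = rng.normal(mean, std) if std > 0 else mean
            idxs = groups[bond]
            delta = tau - ics0.dihedrals[idxs[0]]
            for idx in idxs:
                d[idx] = wrap_degrees(d[idx] + delta)
        ics = ics0.with_values(np.concatenate([b, a, d]))
        confs.append(rebuild_cartesian(ics, g))
    return confs


def torsion_of(conf: Conformer, g: MolecularGraph, bond) -> float:
    """The canonical torsion value around ``bond`` for one conformer."""
    s = canonical_order(coulomb_matrix(g, weighted_graph_distances(g)), g)
    for quad in canonical_torsions(g, s):
        if tuple(sorted((quad[1], quad[2]))) == tuple(sorted(bond)):
            return dihedral_angle(conf.coords, *quad)
    raise ValueError(f"bond {bond} has no canonical torsion")


def exclude_transition_region(confs: list, g: MolecularGraph, bond, band: float):
    """Drop conformers whose key torsion falls in the ±band/2 window around
    the midpoint (along the shorter arc) of the two detected torsion modes.
    Returns (kept, n_removed)."""
    if not 0 < band < 180:
        raise ValueError("band must lie in (0, 180)")
    s = canonical_order(coulomb_matrix(g, weighted_graph_distances(g)), g)
    quad = None
    for q in canonical_torsions(g, s):
        if tuple(sorted((q[1], q[2]))) == tuple(sorted(bond)):
            quad = q
            break
    if quad is None:
        raise ValueError(f"bond {bond} has no canonical torsion")
    vals = np.array([dihedral_angle(c.coords, *quad) for c in confs])
    clusters = cluster_1d(vals, eps=30.0, circular=True)
    if len(clusters) < 2:
        raise ValueError("fewer than 2 torsion modes detected")
    m1 = circular_mean([vals[k] for k in clusters[0]])
    m2 = circular_mean([vals[k] for k in clusters[1]])
    diff = wrap_degrees(m2 - m1)
    mid = wrap_degrees(m1 + diff / 2.0)
    off = np.abs(wrap_degrees(vals - mid))
    drop = off <= band / 2.0
    kept = [c for c, r in zip(confs, drop) if not r]
    return kept, int(drop.sum())
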