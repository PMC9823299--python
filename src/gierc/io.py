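"""Structure file I/O and the GIE-RCM container.

SDF (V2000, multi-record) is the primary format: it carries connectivity and
bond orders, so a molecular graph and a conformer ensemble come straight out
of one file.  XYZ is accepted with a sidecar bond table (two or three
whitespace-separated columns: i j [order], 0-based).  Feature tensors are
stored as an ``.npz`` archive holding the tensor plus a JSON header with the
graph fingerprint, canonical order, padding width, cutoffs and bond-table
version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers conformer ops)

from .bondtable import TABLE_VERSION
from .codec import GIERCM
from .internal import Conformer
from .molgraph import MolecularGraph

__all__ = [
    "graph_from_rdkit",
    "to_rdkit",
    "read_structures",
    "write_structures",
    "save_gierc",
    "load_gierc",
]

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.AROMATIC: 1.5,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
}
_ORDER_BOND = {v: k for k, v in _BOND_ORDER.items()}
_CHI = {
    Chem.ChiralType.CHI_UNSPECIFIED: "none",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "R",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "S",
}
_HYB = {
    Chem.HybridizationType.S: "s",
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


def graph_from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    return MolecularGraph(
        atomic_numbers=tuple(a.GetAtomicNum() for a in mol.GetAtoms()),
        formal_charges=tuple(a.GetFormalCharge() for a in mol.GetAtoms()),
        chirality_tags=tuple(_CHI.get(a.GetChiralTag(), "other") for a in mol.GetAtoms()),
        hybridizations=tuple(_HYB.get(a.GetHybridization(), "sp3") for a in mol.GetAtoms()),
        bonds=tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1.0))
            for b in mol.GetBonds()
        ),
    )


def to_rdkit(g: MolecularGraph, confs: list | None = None) -> Chem.Mol:
    em = Chem.RWMol()
    for z, q in zip(g.atomic_numbers, g.formal_charges):
        a = Chem.Atom(int(z))
        a.SetFormalCharge(int(q))
        a.SetNoImplicit(True)
        em.AddAtom(a)
    for i, j, o in g.bonds:
        em.AddBond(int(i), int(j), _ORDER_BOND.get(float(o), Chem.BondType.SINGLE))
    mol = em.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    if confs:
        for c in confs:
            rc = Chem.Conformer(g.n_atoms)
            for k, xyz in enumerate(c.coords):
                rc.SetAtomPosition(k, tuple(float(v) for v in xyz))
            mol.AddConformer(rc, assignId=True)
    return mol


def read_structures(path, fmt: str | None = None, bond_table=None):
    """Read (MolecularGraph, [Conformer, ...]) from a structure file.

    Multi-record SDF files must contain the same molecule in every record
    (graph identity is enforced); XYZ needs ``bond_table`` (path or list of
    (i, j[, order]) rows, 0-based).
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        graph = None
        confs = []
        for rec, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unreadable record {rec} in {path}")
            g = graph_from_rdkit(mol)
            if graph is None:
                graph = g
            elif (g.atomic_numbers, g.bonds) != (graph.atomic_numbers, graph.bonds):
                raise ValueError(f"record {rec} has a different molecular graph")
            coords = mol.GetConformer().GetPositions()
            confs.append(Conformer(coords=np.array(coords), graph=graph))
        if graph is None:
            raise ValueError(f"no records in {path}")
        return graph, confs
    if fmt == "xyz":
        if bond_table is None:
            raise ValueError("XYZ input requires a bond table")
        if isinstance(bond_table, (str, Path)):
            rows = []
            for line in Path(bond_table).read_text().splitlines():
                parts = line.split()
                if parts and not parts[0].startswith("#"):
                    rows.append(tuple(float(v) for v in parts))
            bond_table = rows
        bonds = tuple(
            (int(r[0]), int(r[1]), float(r[2]) if len(r) > 2 else 1.0)
            for r in bond_table
        )
        symbols, coords_list = _read_xyz(path)
        from .bondtable import SYMBOLS

        sym_to_z = {v: k for k, v in SYMBOLS.items()}
        z = tuple(sym_to_z[s] for s in symbols)
        graph = MolecularGraph(atomic_numbers=z, bonds=bonds)
        return graph, [Conformer(coords=c, graph=graph) for c in coords_list]
    if fmt == "pdb":
        if bond_table is None:
            raise ValueError("PDB input requires a bond table (coordinates only)")
        if isinstance(bond_table, (str, Path)):
            rows = []
            for line in Path(bond_table).read_text().splitlines():
                parts = line.split()
                if parts and not parts[0].startswith("#"):
                    rows.append(tuple(float(v) for v in parts))
            bond_table = rows
        bonds = tuple(
            (int(r[0]), int(r[1]), float(r[2]) if len(r) > 2 else 1.0)
            for r in bond_table
        )
        mol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False,
                                  proximityBonding=False)
        if mol is None:
            raise ValueError(f"unreadable PDB file {path}")
        z = tuple(a.GetAtomicNum() for a in mol.GetAtoms())
        graph = MolecularGraph(atomic_numbers=z, bonds=bonds)
        confs = [
            Conformer(coords=np.array(mol.GetConformer(k).GetPositions()), graph=graph)
            for k in range(mol.GetNumConformers())
        ]
        return graph, confs
    raise ValueError(f"unsupported format {fmt!r}")


def _read_xyz(path):
    lines = Path(path).read_text().splitlines()
    frames, symbols = [], None
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].split()[0])
        block = lines[k + 2 : k + 2 + n]
        syms = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if symbols is None:
            symbols = syms
        elif syms != symbols:
            raise ValueError("XYZ frames differ in atoms")
        frames.append(coords)
        k += 2 + n
    return symbols, frames


def write_structures(confs, g: MolecularGraph, path, fmt: str | None = None,
                     names=None):
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "sdf":
        mol = to_rdkit(g, confs)
        with Chem.SDWriter(str(path)) as w:
            for k in range(mol.GetNumConformers()):
                mol.SetProp("_Name", names[k] if names else f"conf_{k}")
                w.write(mol, confId=k)
        return path
    if fmt == "xyz":
        from .bondtable import SYMBOLS

        out = []
        for k, c in enumerate(confs):
            out.append(str(g.n_atoms))
            out.append(names[k] if names else f"conf_{k}")
            for z, xyz in zip(g.atomic_numbers, c.coords):
                out.append(f"{SYMBOLS.get(z, 'X'):2s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}")
        path.write_text("\n".join(out) + "\n")
        return path
    raise ValueError(f"unsupported format {fmt!r}")


def save_gierc(f: GIERCM, path):
    header = {
        "fingerprint": f.fingerprint,
        "order": list(f.order),
        "m": f.m,
        "rcs": f.rcs,
        "rc": f.rc,
        "bond_table_version": TABLE_VERSION,
    }
    np.savez(path, features=f.features, header=json.dumps(header))
    return Path(path)


def load_gierc(path) -> GIERCM:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        feats = z["features"]
    if header["bond_table_version"] != TABLE_VERSION:
        raise ValueError("feature file was written with a different bond-length table")
    return GIERCM(
        features=feats,
        order=tuple(header["order"]),
        m=int(header["m"]),
        rcs=float(header["rcs"]),
        rc=float(header["rc"]),
        fingerprint=header["fingerprint"],
    )
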