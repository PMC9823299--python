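"""Noise-robustness benchmark of conformation representations.

Three encodings of the same conformer — the GIE-RC feature tensor, the
spanning-tree internal coordinates, and centered Cartesian coordinates — are
flattened, perturbed with a given percentage of multiplicative Gaussian
noise, decoded back to 3D, and compared to the original by all-atom Kabsch
RMSD and by torsion RMSD.  All three routes share the same NeRF rebuilder,
so the representation (not the reconstruction machinery) is the variable
under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import GIERCM, GraphContext, decode, encode
from .internal import (
    Conformer,
    build_tree,
    canonical_torsions,
    rebuild_cartesian,
    to_internal,
    torsion_values,
    wrap_degrees,
)

KINDS = ("gie_rc", "internal", "cartesian")

__all__ = [
    "RepresentationVector",
    "NoiseSpec",
    "to_representation",
    "from_representation",
    "add_percentage_noise",
    "kabsch_rmsd",
    "torsion_rmsd",
    "run_noise_benchmark",
]


@dataclass
class RepresentationVector:
    """A flattened conformation representation plus what is needed to invert
    the flattening (``codec_ref``)."""

    kind: str
    values: np.ndarray
    codec_ref: dict


@dataclass(frozen=True)
class NoiseSpec:
    """Percentage noise: each element x becomes x·(1 + p·ε) with ε standard
    normal (model='multiplicative'), or x + p·σ·ε with σ the vector's scale
    (model='scaled')."""

    percent: float
    seed: int
    model: str = "multiplicative"

    def __post_init__(self):
        if self.percent < 0:
            raise ValueError("noise percentage must be >= 0")
        if self.model not in ("multiplicative", "scaled"):
            raise ValueError(f"unknown noise model {self.model!r}")


def to_representation(conf: Conformer, ctx: GraphContext, kind: str) -> RepresentationVector:
    if kind == "gie_rc":
        f = encode(conf, ctx)
        return RepresentationVector(
            kind=kind,
            values=f.features.ravel().copy(),
            codec_ref={"shape": f.features.shape, "order": f.order, "m": f.m,
                       "fingerprint": f.fingerprint},
        )
    if kind == "internal":
        s = ctx.order_for(conf)
        records = build_tree(ctx.g, s)
        ics = to_internal(conf, records)
        return RepresentationVector(kind=kind, values=ics.flat(),
                                    codec_ref={"ics": ics})
    if kind == "cartesian":
        centered = conf.coords - conf.coords.mean(axis=0)
        return RepresentationVector(kind=kind, values=centered.ravel().copy(),
                                    codec_ref={"n": ctx.g.n_atoms})
    raise ValueError(f"unsupported representation kind {kind!r}")


def from_representation(v: RepresentationVector, ctx: GraphContext) -> Conformer:
    if v.kind == "gie_rc":
        ref = v.codec_ref
        f = GIERCM(features=v.values.reshape(ref["shape"]), order=ref["order"],
                   m=ref["m"], rcs=ctx.rcs, rc=ctx.rc,
                   fingerprint=ref["fingerprint"])
        return decode(f, ctx)
    if v.kind == "internal":
        ics = v.codec_ref["ics"].with_values(v.values)
        return rebuild_cartesian(ics, ctx.g)
    if v.kind == "cartesian":
        return Conformer(coords=v.values.reshape(-1, 3), graph=ctx.g)
    raise ValueError(f"unsupported representation kind {v.kind!r}")


def add_percentage_noise(v: RepresentationVector, spec: NoiseSpec) -> RepresentationVector:
    rng = np.random.default_rng(spec.seed)
    x = v.values
    eps = rng.standard_normal(x.shape)
    if spec.model == "multiplicative":
        noisy = x * (1.0 + spec.percent * eps)
    else:
        sigma = float(np.std(x[x != 0])) if np.any(x != 0) else 0.0
        noisy = np.where(x != 0, x + spec.percent * sigma * eps, x)
    return RepresentationVector(kind=v.kind, values=noisy, codec_ref=v.codec_ref)


def kabsch_rmsd(a: Conformer, b: Conformer) -> float:
    """All-atom RMSD (Å) after optimal proper-rotation superposition (the
    closed-form SVD solution, with the determinant correction so reflections
    are never applied)."""
    pa, pb = a.coords, b.coords
    if pa.shape != pb.shape:
        raise ValueError("atom count mismatch")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    u, _, vt = np.linalg.svd(pa.T @ pb)
    sign = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, sign]) @ vt
    return float(np.sqrt(np.mean(np.sum((pa @ rot - pb) ** 2, axis=1))))


def torsion_rmsd(a: Conformer, b: Conformer, ctx: GraphContext) -> float:
    """RMSD (°) over the canonical torsions (one per non-terminal bond),
    differences wrapped to [−180, 180)."""
    quads = canonical_torsions(ctx.g, ctx.base_order)
    da = torsion_values(a, quads)
    db = torsion_values(b, quads)
    diff = wrap_degrees(da - db)
    return float(np.sqrt(np.mean(diff**2)))


def run_noise_benchmark(
    confs: list,
    ctx: GraphContext,
    levels=(0.0, 2.5, 5.0, 10.0),
    n_pairs: int = 10,
    seed: int = 7,
    kinds=KINDS,
    repeats: int = 1,
    system: str = "synthetic",
    noise_model: str = "multiplicative",
) -> pd.DataFrame:
    """Mean coordinate and torsion RMSD per (representation, noise level).

    Noise levels are percentages (10.0 means p = 0.10).  Each of ``n_pairs``
    conformers is encoded, perturbed with a seeded draw, decoded and compared
    to the original; ``repeats`` independent noise draws are averaged.
    """
    if len(confs) < n_pairs:
        raise ValueError(f"need at least {n_pairs} conformers, got {len(confs)}")
    rows = []
    ss = np.random.SeedSequence(seed)
    for level in levels:
        p = level / 100.0
        cell = {}
        for kind in kinds:
            crmsds, trmsds = [], []
            for rep in range(repeats):
                for idx in range(n_pairs):
                    child = np.random.SeedSequence(
                        entropy=ss.entropy, spawn_key=(int(level * 10), rep, idx)
                    )
                    sub_seed = int(child.generate_state(1)[0] % (2**31))
                    conf = confs[idx]
                    v = to_representation(conf, ctx, kind)
                    if p > 0:
                        v = add_percentage_noise(
                            v, NoiseSpec(percent=p, seed=sub_seed, model=noise_model)
                        )
                    dec = from_representation(v, ctx)
                    crmsds.append(kabsch_rmsd(conf, dec))
                    trmsds.append(torsion_rmsd(conf, dec, ctx))
            cell[f"rmsd_{kind}"] = float(np.mean(crmsds))
            cell[f"torsion_{kind}"] = float(np.mean(trmsds))
        rows.append({
            "system": system, "n_atoms": ctx.g.n_atoms, "noise_percent": level,
            "n_pairs": n_pairs, "repeats": repeats, **cell,
        })
    return pd.DataFrame(rows)
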