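"""Reference bond lengths for weighting the molecular graph.

The weighted 2D graph distance between two atoms is the shortest bond path
where every bond contributes a standard force-field equilibrium length.  The
table below holds MMFF94-style r0 values for the common (element, element,
bond order) triples; any pair missing from it falls back to the sum of the
two covalent radii.  Because the encoder and the decoder read the same table,
the round-trip exactness of the codec does not depend on the table's absolute
accuracy — only on its determinism.
"""

from __future__ import annotations

SYMBOLS = {
    1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 15: "P", 16: "S",
    17: "Cl", 35: "Br", 53: "I",
}

#: Cordero covalent radii, Angstrom.
COVALENT_RADII = {
    1: 0.31, 5: 0.84, 6: 0.76, 7: 0.71, 8: 0.66, 9: 0.57,
    14: 1.11, 15: 1.07, 16: 1.05, 17: 1.02, 35: 1.20, 53: 1.39,
}

#: (Z_low, Z_high, order) -> equilibrium length, Angstrom.  Order 1.5 marks
#: aromatic/conjugated bonds.
BOND_LENGTHS = {
    (1, 1, 1): 0.741,
    (1, 6, 1): 1.093,
    (1, 7, 1): 1.015,
    (1, 8, 1): 0.972,
    (1, 16, 1): 1.340,
    (1, 15, 1): 1.415,
    (6, 6, 1): 1.508,
    (6, 6, 1.5): 1.395,
    (6, 6, 2): 1.333,
    (6, 6, 3): 1.204,
    (6, 7, 1): 1.438,
    (6, 7, 1.5): 1.352,
    (6, 7, 2): 1.270,
    (6, 7, 3): 1.158,
    (6, 8, 1): 1.418,
    (6, 8, 1.5): 1.370,
    (6, 8, 2): 1.222,
    (6, 9, 1): 1.360,
    (6, 15, 1): 1.800,
    (6, 16, 1): 1.805,
    (6, 16, 2): 1.630,
    (6, 17, 1): 1.773,
    (6, 35, 1): 1.941,
    (6, 53, 1): 2.160,
    (7, 7, 1): 1.400,
    (7, 7, 2): 1.245,
    (7, 8, 1): 1.400,
    (7, 8, 2): 1.210,
    (8, 8, 1): 1.480,
    (8, 15, 1): 1.615,
    (8, 15, 2): 1.480,
    (8, 16, 1): 1.658,
    (8, 16, 2): 1.480,
    (15, 16, 2): 1.950,
    (16, 16, 1): 2.050,
}

#: Bump when table contents change; stored in the GIERCM container header so a
#: decode can refuse features produced with a different table.
TABLE_VERSION = "1"


class UnsupportedElementError(ValueError):
    """Raised when neither a table entry nor a covalent radius exists."""


def standard_bond_length(z_i: int, z_j: int, order: float = 1) -> float:
    """Reference length (Å) for a bond between elements ``z_i`` and ``z_j``.

    Looks up the embedded equilibrium-length table keyed by the unordered
    element pair and the bond order; unknown orders retry at order 1, and a
    pair absent from the table falls back to the covalent-radius sum.
    """
    lo, hi = (z_i, z_j) if z_i <= z_j else (z_j, z_i)
    key = (lo, hi, float(order) if order == 1.5 else int(order))
    if key in BOND_LENGTHS:
        return BOND_LENGTHS[key]
    if (lo, hi, 1) in BOND_LENGTHS:
        return BOND_LENGTHS[(lo, hi, 1)]
    try:
        return COVALENT_RADII[z_i] + COVALENT_RADII[z_j]
    except KeyError as exc:
        missing = exc.args[0]
        raise UnsupportedElementError(
            f"no covalent radius for element Z={missing}"
        ) from None
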