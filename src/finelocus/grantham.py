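"""Grantham physicochemical distance between amino acids.

The 20x20 matrix is transcribed from Grantham's published table of mean
chemical difference between amino-acid pairs (composition, polarity and
molecular volume).  Distances range from 5 (Leu/Ile) to 215 (Cys/Trp);
the matrix is symmetric with a zero diagonal.
"""

from __future__ import annotations

__all__ = ["grantham_distance", "GRANTHAM_ORDER"]

#: Row/column order of the published table.
GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"

# Upper triangle, row by row, in GRANTHAM_ORDER.
_UPPER = [
    # S vs R L P T A V G I F Y C H Q N K D E M W
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],
    # R
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],
    # L
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],
    # P
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],
    # T
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],
    # A
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],
    # V
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],
    # G
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],
    # I
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],
    # F
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],
    # Y
    [194, 83, 99, 143, 85, 160, 122, 36, 37],
    # C
    [174, 154, 139, 202, 154, 170, 196, 215],
    # H
    [24, 68, 32, 81, 40, 87, 115],
    # Q
    [46, 53, 61, 29, 101, 130],
    # N
    [94, 23, 42, 142, 174],
    # K
    [101, 56, 95, 110],
    # D
    [45, 160, 181],
    # E
    [126, 152],
    # M
    [67],
]


def _build() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for i, aa in enumerate(GRANTHAM_ORDER):
        table[(aa, aa)] = 0.0
        for offset, value in enumerate(_UPPER[i] if i < len(_UPPER) else []):
            bb = GRANTHAM_ORDER[i + 1 + offset]
            table[(aa, bb)] = float(value)
            table[(bb, aa)] = float(value)
    return table


_TABLE = _build()


def grantham_distance(aa_ref: str, aa_alt: str) -> float:
    """Symmetric Grantham distance between two standard amino acids.

    Single-letter codes, case-insensitive; distance(x, x) = 0.
    Raises ValueError for non-standard residues.
    """
    key = (aa_ref.upper(), aa_alt.upper())
    try:
        return _TABLE[key]
    except KeyError:
        bad = [aa for aa in key if aa not in GRANTHAM_ORDER]
        raise ValueError(f"non-standard amino acid(s): {bad}") from None
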