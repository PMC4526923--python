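"""Amino-acid alphabet, background frequencies and substitution matrices.

All modules share the canonical 20-letter alphabet in the fixed order
``ACDEFGHIKLMNPQRSTVWY``; the ambiguity code ``X`` is tolerated everywhere
and scores zero against every residue in substitution matrices (and emits
the background distribution in profile HMMs).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
X_CODE = len(AA)  # integer code reserved for X

# Residues whose ambiguity/rarity codes are folded into X on input.
AMBIGUOUS = set("BZJUO")

# Robinson & Robinson amino-acid background frequencies (the table HMMER
# ships as its default null model), reordered to AA.
BACKGROUND = np.array(
    [
        0.07805,  # A
        0.01925,  # C
        0.05364,  # D
        0.06295,  # E
        0.03856,  # F
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.05744,  # K
        0.09019,  # L
        0.02243,  # M
        0.04487,  # N
        0.05203,  # P
        0.04264,  # Q
        0.05129,  # R
        0.07120,  # S
        0.05841,  # T
        0.06441,  # V
        0.01330,  # W
        0.03216,  # Y
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM50"):
    """Load a Biopython substitution matrix with X scoring 0 vs everything.

    The returned object is a ``Bio.Align.substitution_matrices.Array`` and
    can be handed directly to ``Bio.Align.PairwiseAligner``.
    """
    mat = substitution_matrices.load(name).copy()
    for c in mat.alphabet:
        mat["X", c] = 0.0
        mat[c, "X"] = 0.0
    return mat


@lru_cache(maxsize=None)
def matrix_lookup(name: str = "BLOSUM50") -> np.ndarray:
    """(21, 21) integer-indexed score table over AA order + X (code 20)."""
    mat = load_matrix(name)
    letters = AA + "X"
    out = np.zeros((21, 21))
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            out[i, j] = mat[a, b]
    return out


def encode(seq: str) -> np.ndarray:
    """Encode a protein sequence as integer codes (X and ambiguity -> 20).

    Raises ``ValueError`` naming the residue and 1-based position for any
    character outside the alphabet.
    """
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        if c in AA_INDEX:
            out[i] = AA_INDEX[c]
        elif c == "X" or c in AMBIGUOUS:
            out[i] = X_CODE
        else:
            raise ValueError(f"unknown residue {c!r} at position {i + 1}")
    return out


def validate_sequence(seq: str) -> None:
    """Raise ValueError on characters outside the 20-letter alphabet + X."""
    encode(seq)
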