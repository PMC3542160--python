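"""Shared sequence helpers.

All internal processing is done on DNA-alphabet uppercase strings (U -> T);
RNA spelling is restored only in report-style output.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: integer encoding used by the folding kernel and vectorised scoring
ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def as_dna(seq: str) -> str:
    """Uppercase and convert RNA spelling to DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Uppercase and convert DNA spelling to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in ENCODE.items():
        out[arr == ord(base)] = code
    return out


def has_degenerate(seq: str) -> bool:
    return any(c not in "ACGT" for c in seq)


def pairs_watson_crick(a: str, b: str) -> bool:
    """True if DNA bases a and b form a Watson-Crick pair (A-T or G-C)."""
    return (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def pairs_wobble(a: str, b: str) -> bool:
    """True if DNA bases a and b form a G-U wobble pair (G-T or T-G)."""
    return (a, b) in {("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or wobble pair."""
    return pairs_watson_crick(a, b) or pairs_wobble(a, b)
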