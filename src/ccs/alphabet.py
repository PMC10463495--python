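"""Amino-acid alphabet and integer encoding.

Residues are encoded as small integers in the classical PAML ordering
(A R N D C Q E G H I L K M F P S T W Y V) so that empirical rate-matrix
constants can be used without reindexing.  Two extra codes represent
missing data: ``GAP`` (alignment gap) and ``UNKNOWN`` (ambiguity codes
and anything else outside the 20 canonical residues).  Both are treated
as fully missing in likelihood computations.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"
N_STATES: int = 20

GAP: int = 20
UNKNOWN: int = 21

#: ambiguity / non-standard one-letter codes mapped to UNKNOWN
AMBIGUOUS: frozenset[str] = frozenset("BZXJUO*?")

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: column permutation that lists the 20 residues in alphabetical order;
#: used to break posterior ties deterministically ('A' before 'C' ...)
ALPHABETICAL_ORDER: np.ndarray = np.array(
    sorted(range(N_STATES), key=lambda i: AMINO_ACIDS[i]), dtype=np.intp
)


def encode_residue(char: str) -> tuple[int, bool]:
    """Encode one residue character.

    Returns ``(code, recognised)`` where ``recognised`` is False for
    characters outside the canonical alphabet, gaps and ambiguity codes
    (the caller may want to log a warning for unrecognised ones).
    """
    c = char.upper()
    if c in _CODE:
        return _CODE[c], True
    if c in ("-", "."):
        return GAP, True
    if c in AMBIGUOUS:
        return UNKNOWN, True
    return UNKNOWN, False


def encode_sequence(seq: str) -> tuple[np.ndarray, list[str]]:
    """Encode a sequence string; returns codes and unrecognised chars."""
    codes = np.empty(len(seq), dtype=np.int8)
    bad: list[str] = []
    for i, ch in enumerate(seq):
        code, ok = encode_residue(ch)
        codes[i] = code
        if not ok:
            bad.append(ch)
    return codes, bad


def decode(codes: np.ndarray, gap_char: str = "-", unknown_char: str = "X") -> str:
    """Decode an integer code vector back to a residue string."""
    out = []
    for c in np.asarray(codes).ravel():
        if c == GAP:
            out.append(gap_char)
        elif c == UNKNOWN:
            out.append(unknown_char)
        else:
            out.append(AMINO_ACIDS[int(c)])
    return "".join(out)


def is_missing(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of cells that carry no state information."""
    return np.asarray(codes) >= N_STATES
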