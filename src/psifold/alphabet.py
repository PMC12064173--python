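"""The four-letter RNA alphabet and sequence encoding.

Nucleotides are indexed A=0, C=1, G=2, U=3 everywhere in the package; this
fixed order is also the tie-break order used when decoding a distribution
to a discrete sequence. DNA input is accepted: T maps to U.
"""

from __future__ import annotations

import numpy as np

from .errors import PsifoldError

ALPHABET = "ACGU"
A, C, G, U = 0, 1, 2, 3

_CHAR_TO_INDEX = {"A": A, "C": C, "G": G, "U": U, "T": U}

#: Canonical base pairs: Watson-Crick plus wobble.
ALLOWED_PAIRS = frozenset(
    {(A, U), (U, A), (C, G), (G, C), (G, U), (U, G)}
)

#: Pairs that do not attract the terminal non-GC (AU/GU) closing penalty.
GC_PAIRS = frozenset({(C, G), (G, C)})


def encode(seq: str) -> np.ndarray:
    """Map a sequence string to an int array (A=0, C=1, G=2, U=3; T -> U).

    Raises :class:`PsifoldError` on any character outside {A,C,G,U,T}
    (case-insensitive).
    """
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = _CHAR_TO_INDEX[ch]
        except KeyError:
            raise PsifoldError(
                f"invalid nucleotide {ch!r} at position {i}; expected A/C/G/U/T"
            ) from None
    return out


def decode_indices(idx: np.ndarray) -> str:
    """Inverse of :func:`encode` (always emits the RNA alphabet)."""
    return "".join(ALPHABET[int(i)] for i in idx)


def pair_symbol(pair: tuple[int, int]) -> str:
    """Render an index pair as a two-letter string such as ``"GC"``."""
    return ALPHABET[pair[0]] + ALPHABET[pair[1]]


def parse_pair(text: str) -> tuple[int, int]:
    """Parse a two-letter pair string such as ``"GC"``; must be pairable."""
    if len(text) != 2:
        raise PsifoldError(f"pair must be two letters, got {text!r}")
    a, b = encode(text)
    if (int(a), int(b)) not in ALLOWED_PAIRS:
        raise PsifoldError(f"{text!r} is not an allowed base pair")
    return int(a), int(b)
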