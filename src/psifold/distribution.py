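"""Probabilistic sequence representation: a product of independent
categorical distributions over {A, C, G, U}, one per position.

The continuous sequence is an ``n x 4`` row-stochastic matrix ``psi``;
one-hot rows recover a discrete sequence. All folding operations accept
either a bare numpy array or a :class:`SequenceDistribution`.
"""

from __future__ import annotations

import numpy as np

from .alphabet import ALPHABET, decode_indices, encode
from .errors import ParseError, PsifoldError

PSI_HEADER = "A\tC\tG\tU"


def as_psi(obj) -> np.ndarray:
    """Coerce to a float64 ``(n, 4)`` matrix without validation."""
    if isinstance(obj, SequenceDistribution):
        return obj.psi
    psi = np.asarray(obj, dtype=np.float64)
    if psi.ndim != 2 or psi.shape[1] != 4:
        raise PsifoldError(f"psi must have shape (n, 4), got {psi.shape}")
    return psi


def validate_psi(psi: np.ndarray, tol: float = 1e-6) -> None:
    """Check rows are (near-)probability vectors; names the offending row."""
    if psi.shape[0] < 1:
        raise PsifoldError("psi must have at least one row")
    if np.any(psi < -tol):
        row = int(np.argwhere(psi < -tol)[0, 0])
        raise PsifoldError(f"psi row {row} has a negative entry")
    sums = psi.sum(axis=1)
    bad = np.abs(sums - 1.0) > tol
    if np.any(bad):
        row = int(np.argmax(bad))
        raise PsifoldError(
            f"psi row {row} sums to {sums[row]:.9g}, not 1 (tolerance {tol:g})"
        )


def one_hot(seq) -> np.ndarray:
    """Degenerate distribution concentrated on a discrete sequence."""
    idx = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int64)
    psi = np.zeros((len(idx), 4))
    psi[np.arange(len(idx)), idx] = 1.0
    return psi


def near_one_hot(seq, eps: float = 1e-3) -> np.ndarray:
    """Rows ``(1 - 3*eps)`` on the given nucleotide, ``eps`` elsewhere.

    Keeps gradients finite away from the simplex vertices; ``eps = 0``
    gives the exact one-hot embedding (gradients may vanish there).
    """
    idx = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int64)
    psi = np.full((len(idx), 4), eps)
    psi[np.arange(len(idx)), idx] = 1.0 - 3.0 * eps
    return psi


def uniform(n: int) -> np.ndarray:
    return np.full((n, 4), 0.25)


def decode(psi) -> str:
    """Per-position argmax; ties break toward the first of A < C < G < U."""
    psi = as_psi(psi)
    return decode_indices(np.argmax(psi, axis=1))


class SequenceDistribution:
    """Validated wrapper around the ``(n, 4)`` probability matrix."""

    def __init__(self, psi, tol: float = 1e-6):
        self.psi = as_psi(psi).copy()
        validate_psi(self.psi, tol=tol)

    @property
    def n(self) -> int:
        return self.psi.shape[0]

    @classmethod
    def from_sequence(cls, seq: str) -> "SequenceDistribution":
        return cls(one_hot(seq))

    def decode(self) -> str:
        return decode(self.psi)

    # ---- TSV I/O: header "A C G U", one row of four probabilities per
    # position ----------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, tol: float = 1e-6) -> "SequenceDistribution":
        rows = []
        with open(path) as fh:
            header = fh.readline().strip()
            if header.split("\t") != list(ALPHABET):
                raise ParseError(f"expected header {PSI_HEADER!r}, got {header!r}", line=1)
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise ParseError(f"expected 4 columns, got {len(fields)}", line=lineno)
                try:
                    rows.append([float(x) for x in fields])
                except ValueError:
                    raise ParseError(f"non-numeric entry in {line.rstrip()!r}", line=lineno)
        if not rows:
            raise ParseError("psi file has no rows")
        try:
            return cls(np.array(rows), tol=tol)
        except PsifoldError as exc:
            raise ParseError(str(exc)) from None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(PSI_HEADER + "\n")
            for row in self.psi:
                fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")
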