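"""Deterministic synthetic fixtures: random sequences, random sequence
distributions, near-one-hot embeddings, and single-stem hairpin design
targets. Same (kind, n, seed) always yields identical output."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import ALPHABET
from .distribution import near_one_hot
from .errors import PsifoldError
from .structure import SecondaryStructure

KINDS = ("random_sequence", "random_distribution", "near_one_hot", "hairpin_target")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n: int
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise PsifoldError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.n < 1:
            raise PsifoldError("fixture length must be >= 1")


def random_sequence(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(ALPHABET[c] for c in rng.integers(0, 4, size=n))


def random_distribution(n: int, seed: int) -> np.ndarray:
    """Rows drawn from a flat Dirichlet over the 4-simplex."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(4), size=n)


def hairpin_target(n: int) -> SecondaryStructure:
    """Single-stem hairpin: stem length floor((n - 3) / 2), loop >= 3."""
    if n < 5:
        raise PsifoldError("hairpin target needs n >= 5")
    stem = (n - 3) // 2
    pairs = [(i, n - 1 - i) for i in range(stem)]
    return SecondaryStructure(n, pairs)


def make_fixture(spec: FixtureSpec):
    """Dispatch on kind; see the individual generators.

    Returns a sequence string, an (n, 4) distribution, or (for
    ``hairpin_target``) a :class:`SecondaryStructure`.
    """
    if spec.kind == "random_sequence":
        return random_sequence(spec.n, spec.seed)
    if spec.kind == "random_distribution":
        return random_distribution(spec.n, spec.seed)
    if spec.kind == "near_one_hot":
        return near_one_hot(random_sequence(spec.n, spec.seed), eps=1e-3)
    return hairpin_target(spec.n)
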