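"""Brute-force reference implementations: the test bedrock.

Everything here is deliberately slow and transparent — exhaustive
enumeration of structures, exhaustive summation over all 4^n sequences, and
entrywise central finite differences — so the dynamic programs can be
checked against code that shares nothing with them but the energy model.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache
from typing import Callable

import numpy as np

from .alphabet import ALLOWED_PAIRS, encode
from .distribution import as_psi
from .errors import PsifoldError
from .params import EnergyModel, default_model
from .structure import SecondaryStructure, structure_energy


def count_structures(n: int, theta: int = 3) -> int:
    """Number of pseudoknot-free structures on n positions, by the standard
    two-term recurrence: the last position is unpaired, or pairs with k
    leaving independent subproblems on either side."""

    @lru_cache(maxsize=None)
    def f(m: int) -> int:
        if m <= theta + 1:
            return 1
        total = f(m - 1)
        # last position (index m-1) pairs with k: needs m-1-k-1 >= theta
        for k in range(0, m - 1 - theta):
            total += f(k) * f(m - k - 2)
        return total

    return f(n)


def enumerate_structures(n: int, theta: int = 3) -> list[SecondaryStructure]:
    """All non-crossing pair sets with loop size >= theta, each exactly once
    (includes the empty structure). Recursion on the last position mirrors
    the counting recurrence, so completeness holds by construction."""
    if n < 0 or theta < 0:
        raise PsifoldError("n and theta must be non-negative")

    @lru_cache(maxsize=None)
    def gen(i: int, j: int) -> tuple[frozenset, ...]:
        # all pair sets on positions i..j inclusive
        if j - i + 1 <= theta + 1:
            return (frozenset(),)
        out = list(gen(i, j - 1))
        for k in range(i, j - theta):
            left = gen(i, k - 1) if k > i else (frozenset(),)
            inside = gen(k + 1, j - 1)
            for a in left:
                for b in inside:
                    out.append(a | b | {(k, j)})
        return tuple(out)

    sets = gen(0, n - 1) if n > 0 else (frozenset(),)
    return [SecondaryStructure(n, ps, theta=theta) for ps in sets]


def brute_partition(seq, model: EnergyModel | None = None, theta: int | None = None) -> float:
    """log Z by explicit enumeration: sum of Boltzmann weights over every
    structure the sequence can form (structures demanding a disallowed pair
    contribute zero). Feasible for n up to ~14."""
    model = model or default_model()
    theta = model.theta if theta is None else theta
    idx = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int64)
    n = len(idx)
    z = 0.0
    for s in enumerate_structures(n, theta=theta):
        if any((int(idx[i]), int(idx[j])) not in ALLOWED_PAIRS for i, j in s.pairs):
            continue
        e = structure_energy(idx, s, model)
        z += model.boltzmann_weight(e)
    return math.log(z)


def brute_expected_partition(psi, model: EnergyModel | None = None) -> float:
    """log E_{pi~psi}[Z_pi] as the explicit weighted sum over all 4^n
    sequences, P(pi|psi) = prod_i psi_i(pi_i). Feasible for n <= ~8.

    Computes the multilinear extension: off-simplex rows are fine.
    """
    model = model or default_model()
    psi = as_psi(psi)
    n = psi.shape[0]
    structures = enumerate_structures(n, theta=model.theta)
    total = 0.0
    for pi in itertools.product(range(4), repeat=n):
        p = 1.0
        for i, c in enumerate(pi):
            p *= psi[i, c]
        if p == 0.0:
            continue
        idx = np.array(pi, dtype=np.int64)
        z = 0.0
        for s in structures:
            if any((int(idx[i]), int(idx[j])) not in ALLOWED_PAIRS for i, j in s.pairs):
                continue
            z += model.boltzmann_weight(structure_energy(idx, s, model))
        total += p * z
    return math.log(total)


def finite_difference_gradient(
    objective: Callable[[np.ndarray], float], psi, h: float = 1e-5
) -> np.ndarray:
    """Central differences entrywise on the unconstrained (n, 4) matrix.

    The objective must accept slightly off-simplex matrices (it is probing
    the multilinear extension). Exact for objectives affine in each entry.
    """
    psi = as_psi(psi).copy()
    grad = np.zeros_like(psi)
    for i in range(psi.shape[0]):
        for c in range(4):
            orig = psi[i, c]
            psi[i, c] = orig + h
            up = objective(psi)
            psi[i, c] = orig - h
            down = objective(psi)
            psi[i, c] = orig
            grad[i, c] = (up - down) / (2.0 * h)
    return grad
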