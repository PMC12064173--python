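"""Secondary structures: well-nested pair sets, dot-bracket I/O, and the
loop decomposition that the energy model is defined over.

A structure on ``n`` positions is a set of 0-based pairs ``(i, j)`` with
``i < j``, no shared endpoints, no crossings (pseudoknot-free), and at least
``theta`` unpaired positions inside every pair (hairpin minimum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .alphabet import ALLOWED_PAIRS, encode, pair_symbol
from .errors import PsifoldError
from .params import EnergyModel


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over ``n`` positions."""

    n: int
    pairs: frozenset[tuple[int, int]]

    def __init__(self, n: int, pairs: Iterable[tuple[int, int]], theta: int = 3):
        pairs = frozenset((int(i), int(j)) for i, j in pairs)
        _validate(n, pairs, theta)
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def from_dotbracket(cls, text: str, theta: int = 3) -> "SecondaryStructure":
        """Parse ``'.'``/``'('``/``')'`` notation."""
        stack: list[int] = []
        pairs = []
        for i, ch in enumerate(text.strip()):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise PsifoldError(f"unbalanced ')' at column {i + 1}")
                pairs.append((stack.pop(), i))
            elif ch != ".":
                raise PsifoldError(f"invalid dot-bracket character {ch!r} at column {i + 1}")
        if stack:
            raise PsifoldError(f"unbalanced '(' at column {stack[-1] + 1}")
        return cls(len(text.strip()), pairs, theta=theta)

    def to_dotbracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairs:
            out[i], out[j] = "(", ")"
        return "".join(out)

    @property
    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def __len__(self) -> int:
        return self.n


def _validate(n: int, pairs: frozenset, theta: int) -> None:
    seen: set[int] = set()
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise PsifoldError(f"pair ({i},{j}) out of range for n={n}")
        if j - i - 1 < theta:
            raise PsifoldError(
                f"pair ({i},{j}) closes a loop of size {j - i - 1} < theta={theta}"
            )
        for x in (i, j):
            if x in seen:
                raise PsifoldError(f"position {x} appears in more than one pair")
            seen.add(x)
    ordered = sorted(pairs)
    for a in range(len(ordered)):
        i, j = ordered[a]
        for b in range(a + 1, len(ordered)):
            k, l = ordered[b]
            if k > j:
                break
            if i < k <= j < l:
                raise PsifoldError(f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknot)")


# ---- loop decomposition ------------------------------------------------


def children_map(s: SecondaryStructure) -> dict:
    """Map each pair (and the exterior key ``None``) to the pairs directly
    nested inside it."""
    result: dict = {None: []}
    stack: list[tuple[int, int]] = []
    for pair in s.sorted_pairs:
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        result.setdefault(pair, [])
        result[parent].append(pair)
        stack.append(pair)
    return result


def loops(s: SecondaryStructure):
    """Decompose a structure into its loops.

    Yields tuples:
      ``("exterior", children)``
      ``("hairpin", closing)``
      ``("stack", closing, inner)``
      ``("internal", closing, inner, left_unpaired, right_unpaired)``
      ``("multiloop", closing, children, unpaired_count)``
    """
    cmap = children_map(s)
    yield ("exterior", tuple(cmap[None]))
    for pair in s.sorted_pairs:
        i, j = pair
        kids = cmap[pair]
        if not kids:
            yield ("hairpin", pair)
        elif len(kids) == 1:
            (k, l) = kids[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                yield ("stack", pair, (k, l))
            else:
                yield ("internal", pair, (k, l), left, right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            yield ("multiloop", pair, tuple(kids), unpaired)


def structure_energy(
    seq: Union[str, Sequence[int], np.ndarray],
    s: SecondaryStructure,
    model: EnergyModel,
) -> float:
    """Free energy (kcal/mol) of ``s`` on ``seq``: the sum of its loop
    energies. Raises if any paired positions cannot form an allowed pair.
    """
    idx = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int64)
    if len(idx) != s.n:
        raise PsifoldError(f"sequence length {len(idx)} != structure length {s.n}")

    def nt_pair(pair):
        p = (int(idx[pair[0]]), int(idx[pair[1]]))
        if p not in ALLOWED_PAIRS:
            raise PsifoldError(
                f"positions {pair} hold {pair_symbol(p)}, not an allowed base pair"
            )
        return p

    total = 0.0
    for loop in loops(s):
        kind = loop[0]
        if kind == "exterior":
            for child in loop[1]:
                nt_pair(child)  # validate even with zero exterior cost
        elif kind == "hairpin":
            (i, j) = loop[1]
            total += model.hairpin_energy(nt_pair(loop[1]), j - i - 1)
        elif kind == "stack":
            total += model.stack_energy(nt_pair(loop[1]), nt_pair(loop[2]))
        elif kind == "internal":
            _, closing, inner, left, right = loop
            total += model.internal_or_bulge_energy(
                nt_pair(closing), nt_pair(inner), left, right
            )
        else:  # multiloop
            _, closing, kids, unpaired = loop
            nt_pair(closing)
            for child in kids:
                nt_pair(child)
            total += model.multiloop_energy(1 + len(kids), unpaired)
    return total
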