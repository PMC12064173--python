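"""Nearest-neighbor loop free energies and Boltzmann weights.

The energy model decomposes a secondary structure's free energy into loop
contributions: size-indexed hairpin initiation, pair-on-pair stacking,
size-indexed bulge/internal initiation (capped), an affine multiloop cost
``a + b*branches + c*unpaired``, and a terminal penalty for non-GC closing
pairs of hairpins and internal/bulge loops. The exterior loop costs zero.
Coaxial stacking, dangling ends, terminal mismatches and tetraloop bonuses
are deliberately outside the model: loop energies depend only on loop sizes
and the closing pair identities, which keeps the brute-force enumeration
oracle exact and the distribution-DP state small.

Energies are in kcal/mol. Boltzmann weights use ``exp(-E / kT)`` with
``kT = 0.61633`` kcal/mol by default (37 degrees C).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from .alphabet import ALLOWED_PAIRS, GC_PAIRS, pair_symbol, parse_pair
from .errors import ParseError, PsifoldError

logger = logging.getLogger("psifold")

Pair = tuple[int, int]

#: Largest loop size with an explicit initiation entry in the default tables.
_TABLE_MAX = 30

#: Jacobson-Stockmayer-style coefficient for extrapolating hairpin initiation
#: beyond the tabulated sizes: E(s) = E(smax) + _LOOP_EXTEND * ln(s / smax).
_LOOP_EXTEND = 1.75 * 0.61633


def _default_hairpin() -> dict[int, float]:
    # anchored at E(3) = 5.4, logarithmic growth
    return {s: round(5.4 + 1.6 * math.log(s / 3.0), 4) for s in range(3, _TABLE_MAX + 1)}


def _default_bulge() -> dict[int, float]:
    # anchored at E(1) = 3.8
    return {s: round(3.8 + 1.6 * math.log(s), 4) for s in range(1, _TABLE_MAX + 1)}


def _default_internal() -> dict[int, float]:
    # anchored at E(4) = 1.7; small loops slightly cheaper but monotone
    tab = {2: 1.0, 3: 1.4}
    tab.update({s: round(1.7 + 1.6 * math.log(s / 4.0), 4) for s in range(4, _TABLE_MAX + 1)})
    return tab


def _default_stack() -> dict[tuple[Pair, Pair], float]:
    """Full directional 6x6 stacking table, Turner-2004-like magnitudes.

    ``stack[(i,j),(k,l)]`` is the energy of pair (k,l) stacked directly
    inside pair (i,j), i.e. the nearest-neighbor step 5'-(i)(k)-3' over
    3'-(j)(l)-5'.
    """
    vals = {
        "AU": {"AU": -0.9, "UA": -1.1, "CG": -2.2, "GC": -2.1, "GU": -0.6, "UG": -1.4},
        "UA": {"AU": -1.3, "UA": -0.9, "CG": -2.4, "GC": -2.1, "GU": -1.0, "UG": -1.3},
        "CG": {"AU": -2.1, "UA": -2.1, "CG": -2.4, "GC": -3.3, "GU": -1.4, "UG": -2.1},
        "GC": {"AU": -2.4, "UA": -2.2, "CG": -3.4, "GC": -3.3, "GU": -1.5, "UG": -2.5},
        "GU": {"AU": -1.3, "UA": -1.4, "CG": -2.5, "GC": -2.1, "GU": -0.5, "UG": -0.4},
        "UG": {"AU": -1.0, "UA": -0.6, "CG": -1.5, "GC": -1.4, "GU": -0.2, "UG": -0.5},
    }
    return {
        (parse_pair(o), parse_pair(i)): e
        for o, inner in vals.items()
        for i, e in inner.items()
    }


@dataclass
class EnergyModel:
    """Loop free-energy parameters plus temperature.

    Attributes
    ----------
    hairpin_init : dict
        Hairpin initiation energy by unpaired loop size (>= ``theta``).
    stack : dict
        Directional stacking energy keyed by (outer pair, inner pair).
    bulge_init, internal_init : dict
        Initiation energy by total unpaired size, up to ``internal_size_cap``.
    multiloop_affine : tuple
        ``(a, b, c)`` = closing + per-branch + per-unpaired cost; the closing
        pair counts as a branch.
    terminal_au : float
        Penalty for a non-GC closing pair of a hairpin or internal/bulge loop.
    kT : float
        Thermal energy in kcal/mol; beta = 1/kT.
    internal_size_cap : int
        Maximum total unpaired size of a bulge/internal loop; larger loops
        get infinite energy (Boltzmann weight zero).
    theta : int
        Minimum hairpin loop size (unpaired nucleotides between a pair).
    """

    hairpin_init: dict[int, float] = field(default_factory=_default_hairpin)
    stack: dict[tuple[Pair, Pair], float] = field(default_factory=_default_stack)
    bulge_init: dict[int, float] = field(default_factory=_default_bulge)
    internal_init: dict[int, float] = field(default_factory=_default_internal)
    multiloop_affine: tuple[float, float, float] = (3.4, 0.4, 0.0)
    terminal_au: float = 0.5
    kT: float = 0.61633
    internal_size_cap: int = 30
    theta: int = 3

    def __post_init__(self):
        if self.kT <= 0:
            raise PsifoldError(f"kT must be positive, got {self.kT}")

    # ---- loop energies -------------------------------------------------

    def terminal_penalty(self, pair: Pair) -> float:
        """Terminal penalty of a closing pair: 0 for GC/CG, else terminal_au."""
        self._check_pair(pair)
        return 0.0 if pair in GC_PAIRS else self.terminal_au

    def hairpin_energy(self, closing_pair: Pair, loop_size: int) -> float:
        if loop_size < self.theta:
            raise PsifoldError(
                f"hairpin loop of size {loop_size} below minimum {self.theta}"
            )
        return self._hairpin_init(loop_size) + self.terminal_penalty(closing_pair)

    def _hairpin_init(self, size: int) -> float:
        try:
            return self.hairpin_init[size]
        except KeyError:
            smax = max(self.hairpin_init)
            if size < smax:
                raise PsifoldError(f"no hairpin initiation entry for size {size}")
            return self.hairpin_init[smax] + _LOOP_EXTEND * math.log(size / smax)

    def stack_energy(self, outer_pair: Pair, inner_pair: Pair) -> float:
        self._check_pair(outer_pair)
        self._check_pair(inner_pair)
        return self.stack[(tuple(outer_pair), tuple(inner_pair))]

    def internal_or_bulge_energy(
        self, outer_pair: Pair, inner_pair: Pair, left_unpaired: int, right_unpaired: int
    ) -> float:
        """Energy of a bulge (one side empty) or internal loop.

        Loops larger than ``internal_size_cap`` are forbidden: +inf.
        """
        self._check_pair(outer_pair)
        self._check_pair(inner_pair)
        size = left_unpaired + right_unpaired
        if size < 1:
            raise PsifoldError("internal/bulge loop needs at least one unpaired base")
        if size > self.internal_size_cap:
            return math.inf
        table = self.internal_init if (left_unpaired > 0 and right_unpaired > 0) else self.bulge_init
        try:
            init = table[size]
        except KeyError:
            raise PsifoldError(f"no loop initiation entry for size {size}") from None
        return init + self.terminal_penalty(outer_pair) + self.terminal_penalty(inner_pair)

    def multiloop_energy(self, branches: int, unpaired: int) -> float:
        if branches < 3:
            raise PsifoldError(
                f"a multiloop has at least 3 branches counting the closing pair, got {branches}"
            )
        a, b, c = self.multiloop_affine
        return a + b * branches + c * unpaired

    def boltzmann_weight(self, e: float) -> float:
        """exp(-e/kT); infinite energy maps to weight 0."""
        if e == math.inf:
            return 0.0
        return math.exp(-e / self.kT)

    # ---- helpers -------------------------------------------------------

    def is_allowed(self, pair: Pair) -> bool:
        return tuple(pair) in ALLOWED_PAIRS

    def _check_pair(self, pair: Pair) -> None:
        if tuple(pair) not in ALLOWED_PAIRS:
            raise PsifoldError(f"{pair_symbol(pair)} is not an allowed base pair")

    def copy(self, **changes) -> "EnergyModel":
        return replace(self, **changes)


def default_model() -> EnergyModel:
    """The toy parameter set shipped with the package."""
    return EnergyModel()


# ---- parameter file I/O ------------------------------------------------
#
# Plain-text key-value format, one record per line, '#' comments:
#   hairpin <size> <kcal/mol>
#   stack <pair> <pair> <kcal/mol>      e.g. stack GC GC -3.3
#   bulge <size> <kcal/mol>
#   internal <size> <kcal/mol>
#   multi <a> <b> <c>
#   terminal_au <kcal/mol>
#   kT <kcal/mol>
#   internal_cap <int>
#   theta <int>


def load_params(path) -> EnergyModel:
    """Load an :class:`EnergyModel` from the documented key-value format.

    Entries missing from the file keep the shipped toy defaults; a warning
    is logged listing which record types fell back.
    """
    model = default_model()
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            key = fields[0]
            try:
                if key == "hairpin":
                    model.hairpin_init[_int(fields[1])] = _float(fields[2])
                elif key == "stack":
                    model.stack[(parse_pair(fields[1]), parse_pair(fields[2]))] = _float(fields[3])
                elif key == "bulge":
                    model.bulge_init[_int(fields[1])] = _float(fields[2])
                elif key == "internal":
                    model.internal_init[_int(fields[1])] = _float(fields[2])
                elif key == "multi":
                    model.multiloop_affine = (_float(fields[1]), _float(fields[2]), _float(fields[3]))
                elif key == "terminal_au":
                    model.terminal_au = _float(fields[1])
                elif key == "kT":
                    model.kT = _float(fields[1])
                elif key == "internal_cap":
                    model.internal_size_cap = _int(fields[1])
                elif key == "theta":
                    model.theta = _int(fields[1])
                else:
                    raise PsifoldError(f"unknown record type {key!r}")
            except (PsifoldError, IndexError) as exc:
                raise ParseError(f"{raw.rstrip()!r}: {exc}", line=lineno) from None
            seen.add(key)
    all_keys = {"hairpin", "stack", "bulge", "internal", "multi",
                "terminal_au", "kT", "internal_cap"}
    missing = sorted(all_keys - seen)
    if missing:
        logger.warning(
            "parameter file %s did not set %s; using shipped defaults",
            path, ", ".join(missing),
        )
    if model.kT <= 0:
        raise ParseError(f"kT must be positive, got {model.kT}")
    return model


def write_params(model: EnergyModel, path) -> None:
    """Write a model in the key-value format; round-trips to full precision."""
    with open(path, "w") as fh:
        fh.write("# psifold energy parameters (kcal/mol)\n")
        fh.write(f"kT {model.kT!r}\n")
        fh.write(f"theta {model.theta}\n")
        fh.write(f"internal_cap {model.internal_size_cap}\n")
        fh.write(f"terminal_au {model.terminal_au!r}\n")
        a, b, c = model.multiloop_affine
        fh.write(f"multi {a!r} {b!r} {c!r}\n")
        for s in sorted(model.hairpin_init):
            fh.write(f"hairpin {s} {model.hairpin_init[s]!r}\n")
        for s in sorted(model.bulge_init):
            fh.write(f"bulge {s} {model.bulge_init[s]!r}\n")
        for s in sorted(model.internal_init):
            fh.write(f"internal {s} {model.internal_init[s]!r}\n")
        for (outer, inner), e in sorted(model.stack.items()):
            fh.write(f"stack {pair_symbol(outer)} {pair_symbol(inner)} {e!r}\n")


def _float(text: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PsifoldError(f"expected a number, got {text!r}") from None


def _int(text: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise PsifoldError(f"expected an integer, got {text!r}") from None
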