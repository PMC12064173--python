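"""Stability-CAI mRNA design over a nucleotide-level sequence distribution.

A coding sequence for a protein of length L has n = 3L nucleotides. The
design objective trades off three terms, all differentiable in psi:

* **ensemble free energy** EFE(psi) = -kT log Z_psi — lower is more stable;
* **expected CAI** — the codon adaptation index generalized to a sequence
  distribution: the product over codon positions of the conditional
  (synonymous-renormalized) expectation of w(c)^(1/L), which reduces to the
  classical CAI (geometric mean of relative adaptiveness weights) at every
  one-hot coding distribution, and factorizes position-wise so it costs
  O(64 L);
* **coding probability** — the probability that a sequence sampled from psi
  translates to the target protein; a product of per-codon synonymous
  masses because positions are independent.

The loss is ``EFE + lambda_cai * max(0, cai_floor - expected_cai)^2
- lambda_code * log(coding_probability)`` (squared-hinge CAI constraint;
the CAI term is dropped when no floor is set).

Reported results are always recomputed from the decoded *discrete*
sequence: its EFE via the discrete partition function and its classical
CAI — never from the relaxed distribution. The returned iterate is the best
CAI-feasible iterate by decoded EFE, so a warm start can never be made
worse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .alphabet import ALPHABET
from .design import Adam, OptimizationTrace, _abort_if_nan, _check_steps, _softmax_vjp, softmax_rows
from .distribution import as_psi, near_one_hot, one_hot
from .errors import ParseError, PsifoldError
from .fold import partition_discrete, value_and_grad_log_z
from .params import EnergyModel, default_model

__all__ = [
    "CODONS",
    "GeneticCode",
    "CAIWeights",
    "CodonDesignSpec",
    "standard_genetic_code",
    "default_cai_weights",
    "codon_marginal",
    "coding_probability",
    "expected_cai",
    "classical_cai",
    "mrna_loss",
    "warm_start",
    "decode_coding",
    "translate",
    "random_coding_sequence",
    "optimize_mrna",
    "MrnaDesignResult",
]

#: The 64 RNA codons in lexicographic A<C<G<U order; index = 16*c1+4*c2+c3.
CODONS = tuple(a + b + c for a in ALPHABET for b in ALPHABET for c in ALPHABET)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


class GeneticCode:
    """Codon -> amino-acid map over the 64 RNA codons; stops map to '*'."""

    def __init__(self, forward: dict[str, str], stops: set[str]):
        table = dict(forward)
        for stop in stops:
            table[stop] = "*"
        if set(table) != set(CODONS):
            missing = sorted(set(CODONS) - set(table))
            raise PsifoldError(f"genetic code is not total; missing {missing[:4]}...")
        self.table = table
        self.stops = frozenset(stops)
        self._by_aa: dict[str, list[str]] = {}
        for codon in CODONS:  # lexicographic order, used for tie-breaks
            self._by_aa.setdefault(table[codon], []).append(codon)

    def translate_codon(self, codon: str) -> str:
        return self.table[codon]

    def codons_for(self, aa: str) -> list[str]:
        try:
            return self._by_aa[aa]
        except KeyError:
            raise PsifoldError(f"no codons for symbol {aa!r}") from None

    @property
    def amino_acids(self) -> list[str]:
        return sorted(a for a in self._by_aa if a != "*")


def standard_genetic_code() -> GeneticCode:
    t = CodonTable.unambiguous_rna_by_id[1]
    return GeneticCode(dict(t.forward_table), set(t.stop_codons))


def translate(seq: str, code: Optional[GeneticCode] = None) -> str:
    """Translate an RNA/DNA coding sequence (length divisible by 3)."""
    code = code or standard_genetic_code()
    seq = seq.upper().replace("T", "U")
    if len(seq) % 3:
        raise PsifoldError(f"coding sequence length {len(seq)} not divisible by 3")
    return "".join(code.translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


# ---------------------------------------------------------------------------
# CAI weights
# ---------------------------------------------------------------------------

# Approximate codon usage of highly expressed E. coli genes (occurrences per
# thousand codons); only relative values within each synonymous family
# matter, since relative adaptiveness divides by the family maximum.
_TOY_USAGE = {
    "UUU": 19.7, "UUC": 18.0, "UUA": 10.2, "UUG": 11.9, "CUU": 10.2,
    "CUC": 10.1, "CUA": 3.2, "CUG": 55.0, "AUU": 29.6, "AUC": 26.6,
    "AUA": 3.7, "AUG": 26.4, "GUU": 19.8, "GUC": 14.3, "GUA": 10.3,
    "GUG": 24.6, "UCU": 8.4, "UCC": 8.9, "UCA": 6.2, "UCG": 8.5,
    "CCU": 6.6, "CCC": 5.4, "CCA": 8.2, "CCG": 23.9, "ACU": 8.7,
    "ACC": 25.0, "ACA": 6.3, "ACG": 14.2, "GCU": 15.7, "GCC": 25.8,
    "GCA": 19.8, "GCG": 34.7, "UAU": 15.9, "UAC": 12.5, "UAA": 1.8,
    "UAG": 0.2, "CAU": 12.6, "CAC": 9.9, "CAA": 14.6, "CAG": 29.3,
    "AAU": 16.8, "AAC": 21.9, "AAA": 34.9, "AAG": 11.1, "GAU": 32.5,
    "GAC": 19.4, "GAA": 40.1, "GAG": 18.3, "UGU": 5.1, "UGC": 6.4,
    "UGA": 0.9, "UGG": 15.1, "CGU": 21.1, "CGC": 22.6, "CGA": 3.5,
    "CGG": 5.3, "AGU": 8.6, "AGC": 16.0, "AGA": 2.0, "AGG": 1.1,
    "GGU": 25.5, "GGC": 29.8, "GGA": 7.8, "GGG": 11.0,
}


class CAIWeights:
    """Relative adaptiveness ``w`` per codon, in (0, 1]; within every
    synonymous family the best codon has w = 1."""

    def __init__(self, w: dict[str, float], code: Optional[GeneticCode] = None):
        code = code or standard_genetic_code()
        self.code = code
        self.w = {}
        for aa in code.amino_acids:
            fam = code.codons_for(aa)
            missing = [c for c in fam if c not in w]
            if missing:
                raise PsifoldError(f"CAI weights missing codons {missing} for {aa!r}")
            vals = {c: float(w[c]) for c in fam}
            top = max(vals.values())
            if top <= 0:
                raise PsifoldError(f"all weights non-positive for amino acid {aa!r}")
            if abs(top - 1.0) > 1e-9:
                raise PsifoldError(
                    f"best synonymous codon for {aa!r} has weight {top}, expected 1; "
                    "use CAIWeights.from_usage to normalize counts"
                )
            for c, v in vals.items():
                if not (0 < v <= 1 + 1e-12):
                    raise PsifoldError(f"weight for {c} must be in (0, 1], got {v}")
                self.w[c] = min(v, 1.0)

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]

    @classmethod
    def from_usage(cls, counts: dict[str, float], code: Optional[GeneticCode] = None) -> "CAIWeights":
        """Relative adaptiveness from codon-usage counts: each codon's
        frequency divided by the most-used synonymous codon's frequency.
        Zero counts are floored to 0.5% of the family maximum so weights
        stay positive (log-CAI stays finite), a standard convention."""
        code = code or standard_genetic_code()
        w: dict[str, float] = {}
        for aa in code.amino_acids:
            fam = code.codons_for(aa)
            top = max(float(counts.get(c, 0.0)) for c in fam)
            if top <= 0:
                raise PsifoldError(f"no usage counts for amino acid {aa!r}")
            for c in fam:
                w[c] = max(float(counts.get(c, 0.0)), 0.005 * top) / top
        return cls(w, code)

    # TSV: `codon<TAB>weight`, RNA alphabet, all 61 sense codons
    @classmethod
    def from_tsv(cls, path, code: Optional[GeneticCode] = None) -> "CAIWeights":
        w: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                fields = line.split()
                if len(fields) != 2:
                    raise ParseError(f"expected 'codon<TAB>weight', got {line!r}", line=lineno)
                codon = fields[0].upper().replace("T", "U")
                if codon not in _CODON_INDEX:
                    raise ParseError(f"invalid codon {fields[0]!r}", line=lineno)
                try:
                    w[codon] = float(fields[1])
                except ValueError:
                    raise ParseError(f"invalid weight {fields[1]!r}", line=lineno)
        try:
            return cls(w, code)
        except PsifoldError as exc:
            raise ParseError(str(exc)) from None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# codon\trelative adaptiveness\n")
            for codon in CODONS:
                if codon in self.w:
                    fh.write(f"{codon}\t{self.w[codon]!r}\n")


def default_cai_weights() -> CAIWeights:
    """Toy weights derived from an approximate E. coli usage table."""
    return CAIWeights.from_usage(_TOY_USAGE)


# ---------------------------------------------------------------------------
# Design spec
# ---------------------------------------------------------------------------


@dataclass
class CodonDesignSpec:
    """Target protein plus loss weights.

    ``lambda_cai``/``lambda_code`` both default to 100 kT. The coding term
    needs a weight that dominates achievable EFE differences: coding for the
    protein is a hard semantic constraint, and a weak penalty leaves the
    relaxed optimum only ~92-97% committed to coding sequences.
    ``cai_floor=None`` means the unconstrained regime (the CAI penalty is
    dropped entirely).
    """

    protein: str
    cai_floor: Optional[float] = None
    lambda_cai: Optional[float] = None
    lambda_code: Optional[float] = None
    code: GeneticCode = field(default_factory=standard_genetic_code)

    def __post_init__(self):
        self.protein = self.protein.strip().upper()
        if not self.protein:
            raise PsifoldError("target protein must be non-empty")
        if "*" in self.protein:
            raise PsifoldError("target protein must not contain a stop symbol")
        for aa in self.protein:
            self.code.codons_for(aa)  # raises on unknown symbols
        if self.cai_floor is not None and not (0.0 <= self.cai_floor <= 1.0):
            raise PsifoldError(f"cai_floor must be in [0, 1], got {self.cai_floor}")

    @property
    def L(self) -> int:
        return len(self.protein)

    @property
    def n(self) -> int:
        return 3 * len(self.protein)

    def lambdas(self, model: EnergyModel) -> tuple[float, float]:
        lc = self.lambda_cai if self.lambda_cai is not None else 100.0 * model.kT
        lg = self.lambda_code if self.lambda_code is not None else 100.0 * model.kT
        return lc, lg


def _check_length(psi: np.ndarray, spec: CodonDesignSpec) -> None:
    if psi.shape[0] != spec.n:
        raise PsifoldError(
            f"psi has {psi.shape[0]} rows but the protein needs n = 3L = {spec.n}"
        )


def _codon_rows(codon: str) -> tuple[int, int, int]:
    i = _CODON_INDEX[codon]
    return i // 16, (i // 4) % 4, i % 4


# ---------------------------------------------------------------------------
# Differentiable codon-level quantities
# ---------------------------------------------------------------------------


def codon_marginal(psi, k: int) -> np.ndarray:
    """Probability of each of the 64 codons at codon position k (product of
    the three nucleotide marginals); sums to 1 on the simplex."""
    psi = as_psi(psi)
    if not (0 <= 3 * k + 2 < psi.shape[0]):
        raise PsifoldError(f"codon index {k} out of range")
    r1, r2, r3 = psi[3 * k], psi[3 * k + 1], psi[3 * k + 2]
    return np.einsum("a,b,c->abc", r1, r2, r3).reshape(64)


def _family_terms(psi: np.ndarray, spec: CodonDesignSpec, k: int, weights=None, wexp=1.0):
    """Per-codon synonymous mass B_k (and weighted mass A_k when weights are
    given) with their gradients w.r.t. the three nucleotide rows."""
    rows = psi[3 * k : 3 * k + 3]
    B = 0.0
    A = 0.0
    gB = np.zeros((3, 4))
    gA = np.zeros((3, 4))
    for codon in spec.code.codons_for(spec.protein[k]):
        c1, c2, c3 = _codon_rows(codon)
        p1, p2, p3 = rows[0, c1], rows[1, c2], rows[2, c3]
        p = p1 * p2 * p3
        B += p
        gB[0, c1] += p2 * p3
        gB[1, c2] += p1 * p3
        gB[2, c3] += p1 * p2
        if weights is not None:
            wv = weights[codon] ** wexp
            A += wv * p
            gA[0, c1] += wv * p2 * p3
            gA[1, c2] += wv * p1 * p3
            gA[2, c3] += wv * p1 * p2
    return A, B, gA, gB


def coding_probability(psi, spec: CodonDesignSpec) -> float:
    """Probability that a sequence sampled from psi codes for the target
    protein: the product over codons of the synonymous-codon mass."""
    psi = as_psi(psi)
    _check_length(psi, spec)
    prob = 1.0
    for k in range(spec.L):
        prob *= _family_terms(psi, spec, k)[1]
    return prob


def _log_coding_and_grad(psi: np.ndarray, spec: CodonDesignSpec) -> tuple[float, np.ndarray]:
    log_p = 0.0
    grad = np.zeros_like(psi)
    for k in range(spec.L):
        _, B, _, gB = _family_terms(psi, spec, k)
        if B <= 0:
            return -math.inf, grad
        log_p += math.log(B)
        grad[3 * k : 3 * k + 3] = gB / B
    return log_p, grad


def expected_cai(psi, spec: CodonDesignSpec, weights: CAIWeights) -> float:
    """Expected CAI of psi conditional on coding for the target protein.

    ``prod_k E_{q_k}[w(c)^(1/L)]`` where q_k is the codon marginal restricted
    to the synonymous family of residue k and renormalized. Conditioning
    factorizes because codon positions are independent, so this equals the
    brute-force E[CAI | coding]. At a one-hot coding psi it is the classical
    CAI. Undefined (raises) when the coding probability is zero.
    """
    val, _ = _expected_cai_and_grad(as_psi(psi), spec, weights)
    return val


def _expected_cai_and_grad(
    psi: np.ndarray, spec: CodonDesignSpec, weights: CAIWeights
) -> tuple[float, np.ndarray]:
    _check_length(psi, spec)
    wexp = 1.0 / spec.L
    val = 1.0
    parts = []
    for k in range(spec.L):
        A, B, gA, gB = _family_terms(psi, spec, k, weights=weights, wexp=wexp)
        if B <= 0:
            raise PsifoldError(
                f"coding probability is zero at codon {k}; expected CAI undefined"
            )
        val *= A / B
        parts.append((A, B, gA, gB))
    grad = np.zeros_like(psi)
    for k, (A, B, gA, gB) in enumerate(parts):
        grad[3 * k : 3 * k + 3] = val * (gA / A - gB / B)
    return val, grad


def classical_cai(seq: str, weights: CAIWeights) -> float:
    """Geometric mean of relative adaptiveness over the codons of a discrete
    coding sequence."""
    seq = seq.upper().replace("T", "U")
    if len(seq) % 3:
        raise PsifoldError(f"coding sequence length {len(seq)} not divisible by 3")
    L = len(seq) // 3
    log_sum = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon not in weights.w:
            raise PsifoldError(f"codon {codon} has no CAI weight (stop codon?)")
        log_sum += math.log(weights[codon])
    return math.exp(log_sum / L)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def mrna_loss(
    psi,
    spec: CodonDesignSpec,
    model: Optional[EnergyModel] = None,
    weights: Optional[CAIWeights] = None,
    scale: float = 1.0,
) -> float:
    """EFE + lambda_cai*hinge(cai_floor - E[CAI])^2 - lambda_code*log P(coding)."""
    loss, _, _ = _mrna_loss_and_grad(
        as_psi(psi), spec, model or default_model(), weights or default_cai_weights(), scale
    )
    return loss


def _mrna_loss_and_grad(
    psi: np.ndarray,
    spec: CodonDesignSpec,
    model: EnergyModel,
    weights: CAIWeights,
    scale: float,
) -> tuple[float, np.ndarray, dict]:
    _check_length(psi, spec)
    lam_cai, lam_code = spec.lambdas(model)
    log_z, gz = value_and_grad_log_z(psi, model, scale=scale, validate=False)
    efe = -model.kT * log_z
    loss = efe
    grad = -model.kT * gz
    cai_val = None
    if spec.cai_floor is not None:
        cai_val, gcai = _expected_cai_and_grad(psi, spec, weights)
        gap = spec.cai_floor - cai_val
        if gap > 0:
            loss += lam_cai * gap * gap
            grad += lam_cai * 2.0 * gap * (-gcai)
    log_code, gcode = _log_coding_and_grad(psi, spec)
    loss += -lam_code * log_code
    grad += -lam_code * gcode
    parts = {"efe": efe, "expected_cai": cai_val, "log_coding": log_code}
    return loss, grad, parts


# ---------------------------------------------------------------------------
# Discrete embeddings and decodings
# ---------------------------------------------------------------------------


def warm_start(coding_sequence: str, spec: CodonDesignSpec, eps: float = 1e-3) -> np.ndarray:
    """Continuous embedding of a discrete coding sequence: near-one-hot rows
    with ``eps`` mass spread off the given nucleotides (gradients stay
    finite). Decoding it recovers the sequence. ``eps=0`` gives the exact
    one-hot embedding, where gradients may vanish at the simplex vertex."""
    seq = coding_sequence.upper().replace("T", "U")
    if translate(seq, spec.code) != spec.protein:
        raise PsifoldError("warm-start sequence does not code for the target protein")
    return near_one_hot(seq, eps=eps)


def random_coding_sequence(spec: CodonDesignSpec, seed: int = 0) -> str:
    """Uniform-synonymous random coding sequence for the target protein."""
    rng = np.random.default_rng(seed)
    out = []
    for aa in spec.protein:
        fam = spec.code.codons_for(aa)
        out.append(fam[rng.integers(len(fam))])
    return "".join(out)


def decode_coding(psi, spec: CodonDesignSpec) -> str:
    """Per-codon argmax of the codon marginal restricted to the synonymous
    family — the output always codes for the protein. Ties break to the
    lexicographically smallest codon."""
    psi = as_psi(psi)
    _check_length(psi, spec)
    out = []
    for k in range(spec.L):
        marg = codon_marginal(psi, k)
        fam = spec.code.codons_for(spec.protein[k])  # lexicographic order
        best = fam[int(np.argmax([marg[_CODON_INDEX[c]] for c in fam]))]
        out.append(best)
    return "".join(out)


def repair_cai(
    seq: str,
    spec: CodonDesignSpec,
    weights: CAIWeights,
    floor: float,
    psi=None,
) -> str:
    """Project a coding sequence onto the CAI-feasible set.

    Argmax decoding rounds the relaxed distribution, which can land just
    below a CAI floor the expectation satisfies. This greedy repair swaps,
    one position at a time, the codon whose upgrade to its family's
    best-adaptiveness codon loses the least marginal probability under
    ``psi`` (or the most CAI per swap when ``psi`` is None), until the
    classical CAI reaches the floor. Terminates because the all-best-codon
    sequence has CAI exactly 1. Deterministic; ties break on position.
    """
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    margs = [codon_marginal(psi, k) for k in range(spec.L)] if psi is not None else None
    while classical_cai("".join(codons), weights) < floor - 1e-12:
        best_k, best_cost = None, None
        for k, codon in enumerate(codons):
            fam = spec.code.codons_for(spec.protein[k])
            maxw = max(weights[c] for c in fam)
            top = next(c for c in fam if weights[c] == maxw)  # fam is lexicographic
            if weights[top] <= weights[codon]:
                continue
            if margs is not None:
                cost = margs[k][_CODON_INDEX[codon]] - margs[k][_CODON_INDEX[top]]
            else:
                cost = -(weights[top] - weights[codon])
            if best_cost is None or cost < best_cost:
                best_k, best_cost = (k, top), cost
        if best_k is None:  # already at maximal CAI everywhere
            break
        codons[best_k[0]] = best_k[1]
    return "".join(codons)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


@dataclass
class MrnaDesignResult:
    """Best coding-feasible iterate with honest discrete-sequence metrics."""

    trace: OptimizationTrace
    sequence: str = ""                 # decoded coding sequence (best iterate)
    efe_discrete: float = 0.0          # -kT log Z of the decoded sequence
    cai_discrete: float = 0.0          # classical CAI of the decoded sequence
    coding_prob: float = 0.0           # coding probability of the final psi
    warm_sequence: str = ""
    warm_efe: float = 0.0
    warm_cai: float = 0.0


def optimize_mrna(
    spec: CodonDesignSpec,
    model: Optional[EnergyModel] = None,
    weights: Optional[CAIWeights] = None,
    warm: Optional[str] = None,
    steps: int = 300,
    learning_rate: float = 0.05,
    seed: int = 0,
    scale: float = 1.0,
) -> MrnaDesignResult:
    """Minimize the stability-CAI loss from a warm start (default: a random
    coding sequence drawn from the seed).

    Every iterate is decoded to a discrete coding sequence and scored by its
    discrete EFE and classical CAI; the reported result is the best decoded
    EFE among iterates meeting the CAI floor (all iterates when no floor or
    none meets it). The warm start is iterate 0, so the reported EFE is
    never worse than the warm start's when the warm start is feasible.
    """
    model = model or default_model()
    weights = weights or default_cai_weights()
    _check_steps(steps)
    if warm is None:
        warm = random_coding_sequence(spec, seed=seed)
    psi0 = warm_start(warm, spec)
    logits = np.log(np.clip(psi0, 1e-12, None))
    opt = Adam(lr=learning_rate)
    trace = OptimizationTrace(param_count=logits.size)

    warm_seq = decode_coding(psi0, spec)
    warm_efe = partition_discrete(warm_seq, model).efe(model)
    warm_cai = classical_cai(warm_seq, weights)

    best = None  # (feasible, efe, seq, psi)
    floor = spec.cai_floor

    def consider(seq: str, psi: np.ndarray):
        nonlocal best
        efe = partition_discrete(seq, model).efe(model)
        cai = classical_cai(seq, weights)
        feasible = (floor is None) or (cai >= floor - 1e-12)
        key = (not feasible, efe)  # feasible first, then lowest EFE
        if best is None or key < best[0]:
            best = (key, seq, psi.copy(), efe, cai)

    for _ in range(steps + 1):
        psi = softmax_rows(logits)
        loss, gpsi, _ = _mrna_loss_and_grad(psi, spec, model, weights, scale)
        glogits = _softmax_vjp(psi, gpsi)
        trace.record(loss, float(np.linalg.norm(glogits)), psi)
        _abort_if_nan(loss, trace)
        decoded = decode_coding(psi, spec)
        consider(decoded, psi)
        if floor is not None and classical_cai(decoded, weights) < floor:
            # constrained decode: project onto the CAI-feasible set. The
            # iterate's psi no longer decodes to the repaired sequence, so
            # the candidate's continuous representative is the sequence's
            # exact embedding.
            repaired = repair_cai(decoded, spec, weights, floor, psi=psi)
            consider(repaired, one_hot(repaired))
        if len(trace.losses) == steps + 1:
            break
        logits = opt.step(logits.ravel(), glogits.ravel()).reshape(spec.n, 4)

    _, seq, best_psi, efe, cai = best
    trace.psi = best_psi
    trace.sequence = seq
    return MrnaDesignResult(
        trace=trace,
        sequence=seq,
        efe_discrete=efe,
        cai_discrete=cai,
        coding_prob=coding_probability(best_psi, spec),
        warm_sequence=warm_seq,
        warm_efe=warm_efe,
        warm_cai=warm_cai,
    )
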