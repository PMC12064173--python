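"""Discrete and expected partition functions by dynamic programming, with
exact gradients.

The discrete partition function of a sequence ``pi`` is

    Z_pi = sum over structures s of exp(-E(s|pi) / kT)      (McCaskill DP)

and the expected partition function of a sequence distribution ``psi`` is

    Z_psi = E_{pi ~ psi}[Z_pi],

computed *exactly* (not by sampling) by a generalized DP whose pair tables
are conditioned on the nucleotide identities at the interval endpoints
(a 4 x 4 block per cell). Because loop energies touch only the closing-pair
positions and loop sizes, conditioning on interval endpoints is sufficient.

Three engineering concerns shape the implementation:

* **Multilinearity.** ``Z_psi`` is affine in each row of ``psi`` separately.
  The DP computes the exact multilinear extension: an unpaired position
  contributes its row sum (1 on the simplex), never a hard-coded 1. This is
  what makes entrywise finite differences of the unconstrained matrix a
  valid oracle for the gradient.

* **Per-nucleotide scaling.** DP entries spanning ``m`` positions are stored
  multiplied by ``scale**(-m)``; the final ``log Z`` adds ``n*log(scale)``
  back. Arithmetic stays in linear space (log-space addition would need a
  smoothed approximation whose gradient is not the gradient of the
  approximation); log-sum-exp appears nowhere in the recursions.

* **Hand-written adjoint.** The gradient of ``log Z_psi`` with respect to
  every entry of ``psi`` is computed by reversing the DP (an inside/outside
  sweep), optionally recomputing pair-table diagonals from checkpoints to
  bound retained memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alphabet import ALLOWED_PAIRS, GC_PAIRS, encode
from .distribution import as_psi, validate_psi
from .errors import NumericalError, PsifoldError
from .params import EnergyModel, default_model
from .structure import SecondaryStructure, children_map

__all__ = [
    "FoldResult",
    "partition_discrete",
    "expected_partition",
    "expected_partition_checkpointed",
    "expected_structure_weight",
    "log_expected_structure_weight",
    "target_structure_probability",
    "gradient",
    "value_and_grad_log_z",
    "value_and_grad_log_target_probability",
    "ensemble_free_energy",
]


@dataclass
class FoldResult:
    """Log (expected) partition function with scaling bookkeeping.

    ``log_z`` is the natural log of Z with the per-nucleotide scaling
    correction ``scale_log = n*log(scale)`` already folded in.
    ``grad_psi`` (if requested) is d log Z / d psi, an ``(n, 4)`` matrix.
    """

    log_z: float
    scale_log: float = 0.0
    grad_psi: Optional[np.ndarray] = None

    def efe(self, model: EnergyModel) -> float:
        """Ensemble free energy -kT * log Z, in kcal/mol."""
        return -model.kT * self.log_z


def ensemble_free_energy(log_z: float, model: EnergyModel) -> float:
    return -model.kT * log_z


# ---------------------------------------------------------------------------
# Precomputed Boltzmann-weight tables
# ---------------------------------------------------------------------------


class _Weights:
    """Boltzmann-weight arrays derived from an :class:`EnergyModel`.

    ``au[a,b]``   weight of the terminal penalty of closing pair (a,b); zero
                  for a disallowed pair, 1 for GC/CG.
    ``pok[a,b]``  1 for allowed pairs else 0.
    ``stackW``    4x4x4x4, outer pair x inner pair.
    ``wh[s]``     hairpin initiation weight by loop size (0 below theta).
    ``wbul/wint`` bulge / internal initiation weight by total size.
    """

    def __init__(self, model: EnergyModel, nmax: int):
        kT = model.kT
        self.kT = kT
        self.theta = model.theta
        self.cap = model.internal_size_cap
        au = np.zeros((4, 4))
        pok = np.zeros((4, 4))
        for pair in ALLOWED_PAIRS:
            pok[pair] = 1.0
            au[pair] = 1.0 if pair in GC_PAIRS else math.exp(-model.terminal_au / kT)
        self.au, self.pok = au, pok
        stackW = np.zeros((4, 4, 4, 4))
        for (outer, inner), e in model.stack.items():
            stackW[outer[0], outer[1], inner[0], inner[1]] = math.exp(-e / kT)
        self.stackW = stackW
        wh = np.zeros(max(nmax, model.theta + 1) + 1)
        for s in range(model.theta, len(wh)):
            wh[s] = math.exp(-model._hairpin_init(s) / kT)
        self.wh = wh
        cap = model.internal_size_cap
        wbul = np.zeros(cap + 1)
        wint = np.zeros(cap + 1)
        for s, e in model.bulge_init.items():
            if s <= cap:
                wbul[s] = math.exp(-e / kT)
        for s, e in model.internal_init.items():
            if s <= cap:
                wint[s] = math.exp(-e / kT)
        self.wbul, self.wint = wbul, wint
        a, b, c = model.multiloop_affine
        self.wa = math.exp(-a / kT)
        self.wb = math.exp(-b / kT)
        self.wc = math.exp(-c / kT)


# ---------------------------------------------------------------------------
# Discrete McCaskill DP
# ---------------------------------------------------------------------------


def partition_discrete(seq, model: Optional[EnergyModel] = None, scale: float = 1.0) -> FoldResult:
    """log Z of a discrete sequence over all pseudoknot-free structures.

    The empty structure always contributes weight 1, so ``exp(log_z) >= 1``
    whenever all energies are finite. Implemented as its own compact DP
    (pair table indexed by actual nucleotides), independent of the
    distribution code path.
    """
    model = model or default_model()
    x = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int64)
    n = len(x)
    if n == 0:
        return FoldResult(0.0, 0.0)
    if scale <= 0:
        raise PsifoldError("scale constant must be positive")
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        return _partition_discrete_core(x, model, scale)


def _partition_discrete_core(x: np.ndarray, model: EnergyModel, scale: float) -> FoldResult:
    n = len(x)
    w = _Weights(model, n)
    theta = w.theta
    inv = 1.0 / scale

    au_pos = w.au[np.ix_(x, x)]  # terminal weight for positions as a pair
    Qb = np.zeros((n, n))
    Y = np.zeros((n, n))  # au_pos * Qb, consumed by internal-loop sums
    Qm = np.zeros((n, n))
    Qm1 = np.zeros((n, n))

    for d in range(theta + 1, n):
        m = n - d
        i = np.arange(m)
        j = i + d
        qb = au_pos[i, j] * (w.wh[d - 1] * inv ** (d + 1))
        if d - 2 >= theta + 1:
            qb = qb + w.stackW[x[i], x[j], x[i + 1], x[j - 1]] * Qb[i + 1, j - 1] * inv**2
        # bulge / internal loops, organized by total unpaired size L
        Lmax = min(w.cap, d - 3 - theta)
        for L in range(1, Lmax + 1):
            dp = d - 2 - L
            kk = np.arange(n - dp)
            yd = Y[kk, kk + dp]
            cs = np.concatenate(([0.0], np.cumsum(yd)))
            win = cs[i + 2 + L] - cs[i + 1]
            ends = yd[i + 1] + yd[i + 1 + L]
            wi, wu = w.wint[L], w.wbul[L]
            qb = qb + au_pos[i, j] * (inv ** (L + 2)) * (wi * win + (wu - wi) * ends)
        # multiloops: closing pair + >= 2 interior branches
        if d >= 2 * theta + 5:
            ml = np.zeros(m)
            for t in range(theta + 3, d - theta - 1):
                ml += Qm[i + 1, i + t - 1] * Qm1[i + t, i + d - 1]
            qb = qb + w.pok[x[i], x[j]] * (w.wa * w.wb * inv**2) * ml
        Qb[i, j] = qb
        Y[i, j] = au_pos[i, j] * qb
        Qm1[i, j] = (w.wc * inv) * Qm1[i, j - 1] + w.wb * qb
        qm = (w.wc * inv) * Qm[i + 1, j] + Qm1[i, j]
        for t in range(theta + 1, d - theta - 1):
            qm = qm + w.wb * Qb[i, i + t] * Qm[i + t + 1, j]
        Qm[i, j] = qm

    F = np.zeros(n + 1)
    F[0] = 1.0
    for jj in range(1, n + 1):
        val = inv * F[jj - 1]
        hi = jj - theta - 1
        if hi > 0:
            val += F[:hi] @ Qb[:hi, jj - 1]
        F[jj] = val
    if not np.isfinite(F[n]) or F[n] <= 0:
        raise NumericalError(
            f"partition DP over/underflowed (scaled Z = {F[n]!r}); adjust the scale constant"
        )
    scale_log = n * math.log(scale)
    return FoldResult(math.log(F[n]) + scale_log, scale_log)


# ---------------------------------------------------------------------------
# Expected partition function: forward DP
# ---------------------------------------------------------------------------


class _Workspace:
    """Primal state of the expected-partition DP.

    Scalar tables (B, Y, Qm, Qm1, F, cumr) are always kept in full; the
    4x4-conditioned pair table ``qb`` is a dict span -> (n-span, 4, 4)
    diagonal and is the object of checkpointing.
    """

    __slots__ = (
        "n", "w", "scale", "inv", "psi", "psis", "r", "cumr",
        "B", "Y", "Qm", "Qm1", "F", "qb", "retain",
    )

    def __init__(self, psi, w: _Weights, scale: float, retain=None):
        n = psi.shape[0]
        self.n = n
        self.w = w
        self.scale = scale
        self.inv = 1.0 / scale
        self.psi = psi
        self.psis = psi * self.inv
        self.r = psi.sum(axis=1)
        self.cumr = np.concatenate(([1.0], np.cumprod(self.r)))
        self.B = np.zeros((n, n))
        self.Y = np.zeros((n, n))
        self.Qm = np.zeros((n, n))
        self.Qm1 = np.zeros((n, n))
        self.F = np.zeros(n + 1)
        self.qb = {}
        self.retain = retain  # None: keep all spans; else a predicate

    def keep(self, d: int) -> bool:
        return self.retain is None or self.retain(d)


def _qb_diag(ws: _Workspace, d: int, qb_dm2: Optional[np.ndarray]) -> np.ndarray:
    """Compute the span-``d`` diagonal of the conditioned pair table.

    ``qb[d][i, a, b]`` is the scaled expected weight of everything strictly
    inside pair (i, i+d), conditional on nucleotides a at i and b at i+d
    (the endpoint psi factors belong to the consumer). Terms: hairpin,
    stack, bulge/internal (by total size, via a sliding-window sum over a
    diagonal of Y), and multiloop closing.
    """
    w, n, inv = ws.w, ws.n, ws.inv
    theta = w.theta
    m = n - d
    i = np.arange(m)
    j = i + d
    rho = ws.cumr[j] / ws.cumr[i + 1]  # product of row sums over i+1..j-1
    s = d - 1
    qb = (w.wh[s] * inv**s) * rho[:, None, None] * w.au[None, :, :]
    if d - 2 >= theta + 1:
        inner = ws.psis[i + 1][:, :, None] * ws.psis[j - 1][:, None, :] * qb_dm2[1 : m + 1]
        qb += np.einsum("abcd,icd->iab", w.stackW, inner)
    Lmax = min(w.cap, d - 3 - theta)
    if Lmax >= 1:
        intl = np.zeros(m)
        for L in range(1, Lmax + 1):
            dp = d - 2 - L
            kk = np.arange(n - dp)
            yd = ws.cumr[kk] * ws.Y[kk, kk + dp] / ws.cumr[kk + dp + 1]
            cs = np.concatenate(([0.0], np.cumsum(yd)))
            win = cs[i + 2 + L] - cs[i + 1]
            ends = yd[i + 1] + yd[i + 1 + L]
            wi, wu = w.wint[L], w.wbul[L]
            intl += (inv**L) * (wi * win + (wu - wi) * ends)
        qb += (rho * intl)[:, None, None] * w.au[None, :, :]
    if d >= 2 * theta + 5:
        ml = np.zeros(m)
        for t in range(theta + 3, d - theta - 1):
            ml += ws.Qm[i + 1, i + t - 1] * ws.Qm1[i + t, i + d - 1]
        qb += (w.wa * w.wb) * ml[:, None, None] * w.pok[None, :, :]
    return qb


def suggest_scale(psi, model: Optional[EnergyModel] = None, probe_len: int = 80) -> float:
    """Per-nucleotide scale constant ``exp(log_z_estimate / n)`` estimated
    from a prefix short enough to fold unscaled. Keeps stored DP entries
    within double range for long sequences."""
    model = model or default_model()
    psi = as_psi(psi)
    n = psi.shape[0]
    if n <= probe_len:
        return 1.0
    probe = expected_partition(psi[:probe_len], model, validate=False)
    return float(math.exp(probe.log_z / probe_len))


def _forward(ws: _Workspace) -> float:
    """Run the span-major forward DP; returns the scaled Z (= F[n])."""
    w, n = ws.w, ws.n
    theta = w.theta
    for d in range(theta + 1, n):
        m = n - d
        i = np.arange(m)
        j = i + d
        qb = _qb_diag(ws, d, ws.qb.get(d - 2))
        ws.qb[d] = qb  # held at least until the span-(d+2) stack term
        pi_, pj_ = ws.psis[:m], ws.psis[d:]
        ws.Y[i, j] = np.einsum("ia,ib,ab,iab->i", pi_, pj_, w.au, qb, optimize=True)
        ws.B[i, j] = np.einsum("ia,ib,iab->i", pi_, pj_, qb, optimize=True)
        ws.Qm1[i, j] = (w.wc * ws.inv) * ws.r[j] * ws.Qm1[i, j - 1] + w.wb * ws.B[i, j]
        qm = (w.wc * ws.inv) * ws.r[i] * ws.Qm[i + 1, j] + ws.Qm1[i, j]
        for t in range(theta + 1, d - theta - 1):
            qm = qm + w.wb * ws.B[i, i + t] * ws.Qm[i + t + 1, j]
        ws.Qm[i, j] = qm
        # span d-2 was consumed by this span's stack term and is never read
        # again going forward; evict unless it is a designated checkpoint
        old = d - 2
        if old in ws.qb and not ws.keep(old):
            del ws.qb[old]
    # final sweep: drop any remaining non-retained diagonal except the two
    # freshest (needed to seed the backward pass)
    for dd in list(ws.qb):
        if dd < n - 3 and not ws.keep(dd):
            del ws.qb[dd]
    ws.F[0] = 1.0
    for jj in range(1, n + 1):
        val = ws.inv * ws.r[jj - 1] * ws.F[jj - 1]
        hi = jj - theta - 1
        if hi > 0:
            val += ws.F[:hi] @ ws.B[:hi, jj - 1]
        ws.F[jj] = val
    z = ws.F[n]
    if not np.isfinite(z) or z <= 0:
        raise NumericalError(
            f"expected-partition DP over/underflowed (scaled Z = {z!r}); "
            "adjust the scale constant"
        )
    return z


# ---------------------------------------------------------------------------
# Expected partition function: reverse sweep (hand adjoint)
# ---------------------------------------------------------------------------


def _get_qb(ws: _Workspace, d: int) -> np.ndarray:
    """Fetch a pair-table diagonal, recomputing the even/odd span chain from
    the nearest retained checkpoint if it was evicted."""
    if d in ws.qb:
        return ws.qb[d]
    chain = []
    c = d
    while c >= ws.w.theta + 1 and c not in ws.qb:
        chain.append(c)
        c -= 2
    for span in reversed(chain):
        ws.qb[span] = _qb_diag(ws, span, ws.qb.get(span - 2))
    return ws.qb[d]


def _backward(ws: _Workspace) -> np.ndarray:
    """Adjoint of log(F[n]) with respect to psi. Mirrors the forward sweep
    exactly, span by span in reverse; cumr adjoints are converted to row-sum
    adjoints at the end."""
    w, n = ws.w, ws.n
    theta = w.theta
    inv = ws.inv
    aB = np.zeros((n, n))
    aY = np.zeros((n, n))
    aQm = np.zeros((n, n))
    aQm1 = np.zeros((n, n))
    aF = np.zeros(n + 1)
    apsis = np.zeros((n, 4))
    ar = np.zeros(n)
    acum = np.zeros(n + 1)
    aqb: dict[int, np.ndarray] = {}

    # exterior
    aF[n] = 1.0 / ws.F[n]
    for jj in range(n, 0, -1):
        a = aF[jj]
        aF[jj - 1] += a * ws.r[jj - 1] * inv
        ar[jj - 1] += a * ws.F[jj - 1] * inv
        hi = jj - theta - 1
        if hi > 0:
            aF[:hi] += a * ws.B[:hi, jj - 1]
            aB[:hi, jj - 1] += a * ws.F[:hi]

    for d in range(n - 1, theta, -1):
        m = n - d
        i = np.arange(m)
        j = i + d
        # --- Qm (first-branch decomposition) -----------------------------
        aqm = aQm[i, j]
        aQm[i + 1, j] += aqm * (w.wc * inv) * ws.r[i]
        ar[i] += aqm * (w.wc * inv) * ws.Qm[i + 1, j]
        aQm1[i, j] += aqm
        for t in range(theta + 1, d - theta - 1):
            aB[i, i + t] += aqm * w.wb * ws.Qm[i + t + 1, j]
            aQm[i + t + 1, j] += aqm * w.wb * ws.B[i, i + t]
        # --- Qm1 ----------------------------------------------------------
        aqm1 = aQm1[i, j]
        aQm1[i, j - 1] += aqm1 * (w.wc * inv) * ws.r[j]
        ar[j] += aqm1 * (w.wc * inv) * ws.Qm1[i, j - 1]
        aB[i, j] += aqm1 * w.wb
        # --- B, Y -> pair table and psi ----------------------------------
        qb = _get_qb(ws, d)
        aBd = aB[i, j]
        aYd = aY[i, j]
        pi_, pj_ = ws.psis[:m], ws.psis[d:]
        outer = pi_[:, :, None] * pj_[:, None, :]
        aqbd = aqb.pop(d, None)
        if aqbd is None:
            aqbd = np.zeros((m, 4, 4))
        aqbd += aBd[:, None, None] * outer + (aYd[:, None, None] * outer) * w.au[None, :, :]
        apsis[:m] += aBd[:, None] * np.einsum("ib,iab->ia", pj_, qb) + aYd[:, None] * np.einsum(
            "ib,ab,iab->ia", pj_, w.au, qb, optimize=True
        )
        apsis[d:] += aBd[:, None] * np.einsum("ia,iab->ib", pi_, qb) + aYd[:, None] * np.einsum(
            "ia,ab,iab->ib", pi_, w.au, qb, optimize=True
        )
        # --- pair-table terms --------------------------------------------
        aS = np.einsum("iab,ab->i", aqbd, w.au)  # shared au contraction
        rho = ws.cumr[j] / ws.cumr[i + 1]
        s = d - 1
        # hairpin
        aR = aS * (w.wh[s] * inv**s)
        acum[j] += aR / ws.cumr[i + 1]
        acum[i + 1] -= aR * rho / ws.cumr[i + 1]
        # stack
        if d - 2 >= theta + 1:
            qb_in = _get_qb(ws, d - 2)[1 : m + 1]
            ainner = np.einsum("abcd,iab->icd", w.stackW, aqbd)
            pin, pjn = ws.psis[i + 1], ws.psis[j - 1]
            block = aqb.setdefault(d - 2, np.zeros((m + 2, 4, 4)))
            block[1 : m + 1] += ainner * (pin[:, :, None] * pjn[:, None, :])
            apsis[i[0] + 1 : i[-1] + 2] += np.einsum(
                "icd,id,icd->ic", ainner, pjn, qb_in, optimize=True
            )
            apsis[j[0] - 1 : j[-1]] += np.einsum(
                "icd,ic,icd->id", ainner, pin, qb_in, optimize=True
            )
        # bulge / internal
        Lmax = min(w.cap, d - 3 - theta)
        if Lmax >= 1:
            intl = np.zeros(m)
            per_L = []
            for L in range(1, Lmax + 1):
                dp = d - 2 - L
                kk = np.arange(n - dp)
                yd = ws.cumr[kk] * ws.Y[kk, kk + dp] / ws.cumr[kk + dp + 1]
                cs = np.concatenate(([0.0], np.cumsum(yd)))
                win = cs[i + 2 + L] - cs[i + 1]
                ends = yd[i + 1] + yd[i + 1 + L]
                wi, wu = w.wint[L], w.wbul[L]
                intl += (inv**L) * (wi * win + (wu - wi) * ends)
                per_L.append((L, dp, kk, yd))
            arho = aS * intl
            acum[j] += arho / ws.cumr[i + 1]
            acum[i + 1] -= arho * rho / ws.cumr[i + 1]
            aT = aS * rho
            for L, dp, kk, yd in per_L:
                aTL = aT * inv**L
                wi, wu = w.wint[L], w.wbul[L]
                ayd = np.zeros(len(yd))
                # adjoint of the sliding-window sum: window over i of length
                # L+1 starting at i+1 -> for each k, sum aTL over
                # i in [k-1-L, k-1] (clipped)
                csA = np.concatenate(([0.0], np.cumsum(aTL)))
                hi_i = np.minimum(len(yd) - 1, np.arange(len(yd)) - 1)
                hi_i = np.minimum(hi_i, m - 1)
                lo_i = np.maximum(0, np.arange(len(yd)) - 1 - L)
                valid = hi_i >= lo_i
                ayd[valid] += wi * (csA[hi_i[valid] + 1] - csA[lo_i[valid]])
                ayd[i + 1] += (wu - wi) * aTL
                ayd[i + 1 + L] += (wu - wi) * aTL
                denom = ws.cumr[kk + dp + 1]
                aY[kk, kk + dp] += ayd * ws.cumr[kk] / denom
                acum[kk] += ayd * ws.Y[kk, kk + dp] / denom
                acum[kk + dp + 1] -= ayd * yd / denom
        # multiloop closing
        if d >= 2 * theta + 5:
            aml = np.einsum("iab,ab->i", aqbd, w.pok) * (w.wa * w.wb)
            for t in range(theta + 3, d - theta - 1):
                aQm[i + 1, i + t - 1] += aml * ws.Qm1[i + t, i + d - 1]
                aQm1[i + t, i + d - 1] += aml * ws.Qm[i + 1, i + t - 1]
        # past spans d and d+1 are never needed again
        for dd in (d + 1, d):
            if dd in ws.qb and not ws.keep(dd):
                del ws.qb[dd]
        aqb.pop(d + 1, None)

    # cumr[k] = prod(r[:k]) : ar[t] += sum_{k > t} acum[k]*cumr[k] / r[t]
    g = acum * ws.cumr
    tail = np.cumsum(g[::-1])[::-1][1:]  # tail[t] = sum_{k > t} acum[k]*cumr[k]
    ar += tail / ws.r
    grad = apsis * inv + ar[:, None]
    return grad


# ---------------------------------------------------------------------------
# Public expected-partition API
# ---------------------------------------------------------------------------


def expected_partition(
    psi,
    model: Optional[EnergyModel] = None,
    scale: float = 1.0,
    grad: bool = False,
    checkpoint_every: Optional[int] = None,
    validate: bool = True,
    tol: float = 1e-6,
) -> FoldResult:
    """log of the expected partition function ``E_{pi~psi}[Z_pi]``.

    Parameters
    ----------
    psi : (n, 4) array or SequenceDistribution
        Row-stochastic sequence distribution.
    scale : float
        Per-nucleotide scale constant; the reported ``log_z`` is independent
        of it. Choose roughly ``exp(log_z / n)`` to keep stored DP entries
        near 1 for long sequences.
    grad : bool
        Also compute ``d log Z / d psi`` by the reverse sweep.
    checkpoint_every : int or None
        If set (1 <= k <= n), retain only two pair-table diagonals per block
        of ``k`` spans during the forward pass and recompute the rest during
        the reverse sweep. Results are identical to the full path.
    validate : bool
        Verify rows lie on the probability simplex (within ``tol``). Off-
        simplex evaluation of the multilinear extension is permitted with
        ``validate=False`` (used by the finite-difference oracle).
    """
    model = model or default_model()
    psi = as_psi(psi)
    if validate:
        validate_psi(psi, tol=tol)
    if psi.shape[0] < 1:
        raise PsifoldError("psi must have at least one row")
    if scale <= 0:
        raise PsifoldError("scale constant must be positive")
    n = psi.shape[0]
    retain = None
    if checkpoint_every is not None:
        k = int(checkpoint_every)
        if not (1 <= k <= max(n, 1)):
            raise PsifoldError(f"checkpoint_every must be in [1, n], got {checkpoint_every}")
        s0 = model.theta + 1
        retain = lambda d, k=k, s0=s0: ((d - s0) % k) >= k - 2  # noqa: E731
    w = _Weights(model, n)
    ws = _Workspace(psi, w, scale, retain=retain)
    # over/underflow surfaces as a NumericalError on the final Z, not as
    # numpy warnings along the way
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        z = _forward(ws)
        scale_log = n * math.log(scale)
        log_z = math.log(z) + scale_log
        g = _backward(ws) if grad else None
    return FoldResult(log_z, scale_log, g)


def expected_partition_checkpointed(
    psi,
    model: Optional[EnergyModel] = None,
    checkpoint_every: int = 1,
    scale: float = 1.0,
    grad: bool = True,
    validate: bool = True,
) -> FoldResult:
    """Checkpointed gradient path; caller-visible values match the full
    path (see ``expected_partition``)."""
    return expected_partition(
        psi,
        model,
        scale=scale,
        grad=grad,
        checkpoint_every=checkpoint_every,
        validate=validate,
    )


# ---------------------------------------------------------------------------
# Expected weight of one fixed structure (tree DP over its loops)
# ---------------------------------------------------------------------------


def _structure_weight_scaled(psi, s: SecondaryStructure, w: _Weights, scale: float) -> float:
    """E_{pi~psi}[exp(-E(s|pi)/kT)] * scale**(-n).

    Factorizes over the loop tree of ``s``: each pair carries a 4x4 message
    conditional on its endpoint nucleotides; sequences with a disallowed
    pair at a paired position contribute zero (the ``au``/``pok`` factors
    vanish there).
    """
    psi = as_psi(psi)
    n = psi.shape[0]
    if s.n != n:
        raise PsifoldError(f"structure length {s.n} != psi length {n}")
    inv = 1.0 / scale
    psis = psi * inv
    r = psi.sum(axis=1)

    def runp(lo: int, hi: int) -> float:
        # product of row sums (scaled) over positions lo..hi inclusive
        if hi < lo:
            return 1.0
        return float(np.prod(r[lo : hi + 1])) * inv ** (hi - lo + 1)

    cmap = children_map(s)

    def message(pair) -> np.ndarray:
        i, j = pair
        kids = cmap[pair]
        if not kids:
            size = j - i - 1
            if size < w.theta:
                raise PsifoldError(f"hairpin ({i},{j}) below minimum loop size")
            return w.au * (w.wh[size] * runp(i + 1, j - 1))
        if len(kids) == 1:
            (k, l) = kids[0]
            msgk = message(kids[0])
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                inner = psis[k][:, None] * psis[l][None, :] * msgk
                return np.einsum("abcd,cd->ab", w.stackW, inner)
            L = left + right
            if L > w.cap:
                return np.zeros((4, 4))
            wsz = w.wint[L] if (left > 0 and right > 0) else w.wbul[L]
            inner = float(
                np.einsum("c,d,cd,cd->", psis[k], psis[l], w.au, msgk)
            )
            return w.au * (wsz * runp(i + 1, k - 1) * runp(l + 1, j - 1) * inner)
        # multiloop: closing pair contributes wa*wb, each branch wb, each
        # unpaired nucleotide wc (times its scaled row sum)
        val = w.wa * w.wb
        prev = i
        for kid in kids:
            k, l = kid
            if k - 1 >= prev + 1:
                val *= runp(prev + 1, k - 1) * w.wc ** (k - 1 - prev)
            msgk = message(kid)
            val *= w.wb * float(np.einsum("c,d,cd->", psis[k], psis[l], msgk))
            prev = l
        if j - 1 >= prev + 1:
            val *= runp(prev + 1, j - 1) * w.wc ** (j - 1 - prev)
        return w.pok * val

    total = 1.0
    prev = -1
    for kid in cmap[None]:
        k, l = kid
        total *= runp(prev + 1, k - 1)
        msgk = message(kid)
        total *= float(np.einsum("c,d,cd->", psis[k], psis[l], msgk))
        prev = l
    total *= runp(prev + 1, n - 1)
    return total


def expected_structure_weight(
    psi, s: SecondaryStructure, model: Optional[EnergyModel] = None
) -> float:
    """E_{pi~psi}[exp(-E(s|pi)/kT)] for one fixed structure.

    For a one-hot ``psi`` this is ``exp(-structure_energy/kT)`` of the
    underlying sequence (zero if the sequence cannot form ``s``); the empty
    structure always has weight 1.
    """
    model = model or default_model()
    psi = as_psi(psi)
    w = _Weights(model, psi.shape[0])
    return _structure_weight_scaled(psi, s, w, 1.0)


def log_expected_structure_weight(
    psi, s: SecondaryStructure, model: Optional[EnergyModel] = None, scale: float = 1.0
) -> float:
    """log E[exp(-E(s|pi)/kT)] with per-nucleotide scaling for long helices."""
    model = model or default_model()
    psi = as_psi(psi)
    w = _Weights(model, psi.shape[0])
    val = _structure_weight_scaled(psi, s, w, scale)
    if val <= 0:
        return -math.inf
    return math.log(val) + psi.shape[0] * math.log(scale)


def target_structure_probability(
    psi,
    s: SecondaryStructure,
    model: Optional[EnergyModel] = None,
    scale: float = 1.0,
    validate: bool = True,
) -> float:
    """Probability-like design score: E[e^{-beta E(s|pi)}] / E[Z_pi].

    A ratio of expectations; for a one-hot ``psi`` it is exactly the
    Boltzmann probability of ``s`` for that sequence. Always <= 1, since the
    numerator is one summand class of the denominator's expectation.
    """
    model = model or default_model()
    psi = as_psi(psi)
    if validate:
        validate_psi(psi)
    w = _Weights(model, psi.shape[0])
    num = _structure_weight_scaled(psi, s, w, scale)
    ws = _Workspace(psi, w, scale)
    den = _forward(ws)
    return num / den


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------


def value_and_grad_log_z(
    psi,
    model: Optional[EnergyModel] = None,
    scale: float = 1.0,
    checkpoint_every: Optional[int] = None,
    validate: bool = True,
) -> tuple[float, np.ndarray]:
    res = expected_partition(
        psi, model, scale=scale, grad=True,
        checkpoint_every=checkpoint_every, validate=validate,
    )
    return res.log_z, res.grad_psi


def _structure_weight_row_grads(
    psi: np.ndarray, s: SecondaryStructure, w: _Weights, scale: float
) -> np.ndarray:
    """d W_scaled / d psi by multilinearity: entry (i, c) equals the weight
    with row i replaced by the one-hot on c (exact, since W is affine in
    each row)."""
    n = psi.shape[0]
    grads = np.zeros((n, 4))
    for i in range(n):
        saved = psi[i].copy()
        for c in range(4):
            psi[i] = 0.0
            psi[i, c] = 1.0
            grads[i, c] = _structure_weight_scaled(psi, s, w, scale)
        psi[i] = saved
    return grads


def value_and_grad_log_target_probability(
    psi,
    s: SecondaryStructure,
    model: Optional[EnergyModel] = None,
    scale: float = 1.0,
    validate: bool = True,
) -> tuple[float, np.ndarray]:
    """log p(target) and its gradient w.r.t. psi.

    ``log p = log W - log Z``; the W-part uses the multilinearity of the
    expected structure weight, the Z-part the DP adjoint.
    """
    model = model or default_model()
    psi = as_psi(psi).copy()
    if validate:
        validate_psi(psi)
    w = _Weights(model, psi.shape[0])
    wval = _structure_weight_scaled(psi, s, w, scale)
    if wval <= 0:
        raise NumericalError(
            "target structure has zero expected weight under psi; "
            "log-probability undefined"
        )
    gw = _structure_weight_row_grads(psi, s, w, scale) / wval
    log_z, gz = value_and_grad_log_z(psi, model, scale=scale, validate=False)
    n = psi.shape[0]
    log_p = (math.log(wval) + n * math.log(scale)) - log_z
    return log_p, gw - gz


def gradient(
    psi,
    model: Optional[EnergyModel] = None,
    objective: str = "log_expected_partition",
    target: Optional[SecondaryStructure] = None,
    scale: float = 1.0,
    efe_weight: float = 1.0,
    validate: bool = True,
) -> np.ndarray:
    """Exact gradient of a scalar objective with respect to every psi entry.

    Objectives:

    * ``log_expected_partition`` : log Z_psi
    * ``target_structure_probability`` : p(target) (requires ``target``)
    * ``composite`` : -log p(target) + efe_weight * (-kT log Z_psi), the
      structure-design loss with an ensemble-stability term.

    The gradient is with respect to the unconstrained matrix (simplex
    handling is the caller's parameterization).
    """
    model = model or default_model()
    if objective == "log_expected_partition":
        return value_and_grad_log_z(psi, model, scale=scale, validate=validate)[1]
    if target is None:
        raise PsifoldError(f"objective {objective!r} requires a target structure")
    if objective == "target_structure_probability":
        log_p, g = value_and_grad_log_target_probability(
            psi, target, model, scale=scale, validate=validate
        )
        return math.exp(log_p) * g
    if objective == "composite":
        log_p, gp = value_and_grad_log_target_probability(
            psi, target, model, scale=scale, validate=validate
        )
        _, gz = value_and_grad_log_z(psi, model, scale=scale, validate=False)
        return -gp + efe_weight * (-model.kT) * gz
    raise PsifoldError(f"unknown objective {objective!r}")
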