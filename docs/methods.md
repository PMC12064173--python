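# Methods

## Model

psifold computes the Boltzmann ensemble of RNA secondary structures under a
reduced nearest-neighbor thermodynamic model, for discrete sequences and —
the point of the package — for *distributions* over sequences.

A structure `s` on `n` positions is a non-crossing set of base pairs
(AU/UA, CG/GC, GU/UG) with at least `theta = 3` unpaired nucleotides inside
every pair. Its free energy decomposes over loops:

* hairpin initiation, indexed by loop size (tabulated for sizes 3–30,
  logarithmic Jacobson–Stockmayer-style extrapolation beyond);
* stacking, a directional 6x6 table over (outer pair, inner pair);
* bulge and internal-loop initiation indexed by total unpaired size, capped
  at 30 (larger loops are forbidden: infinite energy, zero weight);
* affine multiloops `a + b*branches + c*unpaired`, the closing pair
  counting as a branch;
* a terminal penalty for non-GC closing pairs of hairpins and
  internal/bulge loops;
* a zero-cost exterior loop.

Coaxial stacking, dangling ends, terminal mismatches, and tetraloop bonuses
are deliberately excluded. This keeps loop energies a function of loop
sizes and closing-pair identities only, which (a) lets the brute-force
enumeration oracle be *exact*, and (b) keeps the distribution-DP state at a
4x4 block per cell (endpoint nucleotides only). Lonely pairs are allowed.

The shipped toy parameter set pins a handful of values (hairpin[3] = 5.4,
stack(GC,GC) = -3.3, stack(AU,UA) = -1.1, bulge[1] = 3.8, internal[4] =
1.7, multiloop (3.4, 0.4, 0.0), terminal penalty 0.5 kcal/mol) and fills
the remaining tables once with Turner-2004-like magnitudes; GC-rich stacks
are strongest, wobble stacks weakest. `kT = 0.61633` kcal/mol (37 C). The
toy set is physically plausible but *not* a fit to experiment; results
under it are qualitative.

## Discrete and expected partition functions

For a discrete sequence, `Z = sum_s exp(-E(s)/kT)` is computed by the
standard inside recursion over interval spans (pair table, multiloop
fragment tables with an unambiguous first/last-branch decomposition, and an
exterior prefix sweep). The empty structure contributes weight 1, so the
ensemble free energy `EFE = -kT log Z` is never positive.

For a sequence distribution — an `n x 4` row-stochastic matrix `psi`, one
independent categorical per position — the package computes the exact
expectation `Z_psi = E_{pi~psi}[Z_pi]`, a weighted sum over all `4^n`
sequences. Because every loop energy touches only its closing-pair
positions, it suffices to condition each pair-table cell on the nucleotide
identities at its two endpoints (a 4x4 block); interior positions are
marginalized as they are consumed. Internal loops are summed by total size
with a sliding-window cumulative sum over a diagonal of the
au-weighted pair table, so the reference `O(cap^2)` double loop collapses
to `O(cap)` vectorized passes per span without changing any value.

Two conventions matter downstream:

* **Multilinear extension.** `Z_psi` is affine in each row of `psi`
  separately. The DP implements the extension exactly — an unpaired
  position contributes its row sum, never a hard-coded 1 — so evaluating at
  slightly off-simplex matrices is well defined. This is what makes
  entrywise central finite differences a valid oracle for the gradient, and
  row-mixing linearity a testable property. Public entry points validate
  rows to 1e-6 by default; oracles evaluate with validation off.
* **Per-nucleotide scaling.** DP entries spanning `m` positions are stored
  multiplied by `scale^-m`; `n log(scale)` is added back at the end, and the
  reported `log Z` is independent of `scale` to machine precision.
  Arithmetic stays in linear space: log-space addition needs a smoothed
  approximation whose gradient is not the gradient of the approximation.
  A helper estimates `scale ~ exp(log_z/n)` from a prefix; with it the DP
  is stable to n = 500 and beyond (unscaled, double precision overflows
  near log Z ~ 700). Scale powers are applied incrementally per term, never
  as global prefix products, so no auxiliary vector spans the full dynamic
  range.

## Gradients

`d log Z_psi / d psi` is computed by a hand-written reverse sweep (an
inside/outside pass): the exterior recursion, then each span in descending
order, propagating adjoints through the same terms the forward pass
evaluated — multiloop fragments first, then the pair-table terms (hairpin,
stack, internal-window, multiloop closing), finally converting
cumulative-row-product adjoints into per-row ones. Correctness is pinned by
central finite differences entrywise (tolerance 1e-4 relative; observed
agreement ~1e-9).

The gradient of the expected weight of one *fixed* structure uses
multilinearity directly: the derivative with respect to row `i` equals the
weight with that row replaced by each one-hot, giving `4n` cheap tree-DP
evaluations — exact, and independent of the adjoint code path.

**Checkpointing.** The memory hot spot of the reverse sweep is the
4x4-conditioned pair table. With `checkpoint_every = k`, the forward pass
retains only the top two span-diagonals of every block of `k` spans (a
span's recomputation needs only its span-2 predecessor, through the stack
term; the O(n^2) scalar tables are always kept), and the reverse sweep
recomputes the evicted diagonals block by block. Retained pair-table
diagonals are `2(n/k) + k` instead of `n`, minimized at `k ~ sqrt(2n)`.
Caller-visible values are bit-identical to the full path; that equality is
the tested contract.

## Structure design

The target-structure objective is the *ratio of expectations*
`p(target|psi) = E[exp(-E(s|pi)/kT)] / E[Z_pi]`: a single scalar in (0, 1]
that equals the Boltzmann probability of the target exactly at one-hot
`psi` (the convention is pinned by that limit and by the enumeration
oracle). The design loss is `-log p`.

Optimization is Adam (lr 0.05, 500 steps by default) over either

* the logits of `psi` directly (row-wise softmax), starting from uniform, or
* the weights of a small fully connected generator (input: a fixed
  16-dimensional standard-normal vector drawn once from the seed; two
  tanh hidden layers of 64 units; linear output reshaped to `n x 4` logits,
  Xavier initialization). Gradients flow through the folding DP into the
  weights; backprop through the network is hand-written and
  finite-difference checked.

Runs are deterministic given the seed. The returned distribution is the
best iterate by loss, and the reported "final probability" is always
recomputed from the decoded discrete sequence (per-position argmax, ties to
A < C < G < U) via the *discrete* partition function — never from the
relaxed distribution.

On the toy single-stem hairpin fixture both paths converge to
near-maximal target probability; the direct path reaches the global
GC-alternating optimum from a uniform start, so this fixture exercises
correctness and determinism of the generator path rather than the
harder-landscape regime where overparameterized search is expected to pull
ahead of direct descent. The acceptance script reports the per-seed
comparison as measured.

## mRNA design

For a protein of length `L` (coding sequence `n = 3L`), the loss is

    EFE(psi) + lambda_cai * max(0, cai_floor - ECAI(psi))^2
             - lambda_code * log P(coding | psi)

* `P(coding)` is the product over codon positions of the synonymous-codon
  mass of the codon marginal (positions are independent).
* `ECAI`, the expected codon adaptation index, is the product over codons
  of the conditional (synonymous-renormalized) expectation of `w(c)^(1/L)`.
  Conditioning factorizes position-wise, so this equals the brute-force
  `E[CAI | coding]` at `O(64 L)` cost and reduces to the classical CAI
  (geometric mean of relative adaptiveness) at every one-hot coding `psi` —
  the limit that pins the convention.
* Both lambda weights default to `100 kT`. The coding weight in particular
  must dominate achievable EFE differences: coding for the protein is a
  hard semantic constraint, and with a weak penalty the relaxed optimum
  commits only ~92–97% of its mass to coding sequences, because the
  expected partition function rewards mixing toward stable non-coding
  sequences.

Optimization runs from a warm start (a supplied coding sequence, or a
uniform-synonymous random one drawn from the seed), embedded as
near-one-hot rows with 1e-3 off-mass so gradients are finite. Every iterate
is decoded codon-wise (argmax restricted to the synonymous family, so the
output always codes), and scored by its *discrete* EFE and classical CAI.
When a CAI floor is set and the argmax decode lands below it — the hinge
constrains the expectation, and rounding can fall short — a deterministic
round-then-repair projection upgrades, one codon at a time, the position
whose switch to its family's best-adaptiveness codon costs the least
marginal probability, until the floor is met. The reported result is the
best decoded EFE among floor-feasible candidates (all candidates when no
floor is set or none is feasible); the warm start is candidate zero, so the
reported EFE never exceeds a feasible warm start's. When the reported
sequence comes from a repair, the reported `psi` is that sequence's exact
one-hot embedding, since the iterate's `psi` no longer decodes to it.

The toy study peptide is MGRAL (Met plus four high-degeneracy residues;
576 coding sequences), and the toy relative-adaptiveness table is derived
from an approximate usage profile of highly expressed E. coli genes, in
which G/C-ending codons are usually favored — a realistic coupling between
codon optimality and the GC content that stabilizes structure.

## Synthetic data

Fixtures are generated programmatically and are byte-deterministic in
(kind, n, seed): uniform-random sequences, flat-Dirichlet random
distributions, near-one-hot embeddings (eps = 1e-3), and single-stem
hairpin targets of stem length `floor((n-3)/2)`. They emulate the *inputs*
of the method — sequences, relaxed sequence distributions, design targets —
not real transcriptomes: there is no sequence composition bias, no
evolved structure, and the toy energy tables are not fitted, so passing
tests certify the algorithms (oracle equivalence, exact gradients,
invariances, optimization contracts), not predictive accuracy on real RNA.

## Numerical choices and degenerate inputs

* Oracle size caps: structure enumeration to n = 14, sequence brute force
  to n = 7–8, chosen to keep the full suite at desk scale (the whole test
  run completes in a few minutes).
* Test problem sizes: gradient checks to n = 15; invariance checks at
  n = 30–80; one-hot consistency to n = 60; a scaling stress run at n = 500.
* `n < theta + 2` folds to `log Z = 0` by construction, not an error.
* Over/underflow in a DP surfaces as a single `NumericalError` naming the
  scaled Z, not as numpy warnings.
* Ties: decoding breaks toward A < C < G < U; codon-restricted decoding and
  CAI repair break toward the lexicographically smallest codon; repair
  ties break toward the earliest position.
* Parameter files round-trip at full precision (`repr` floats); entries
  missing from a file keep the shipped defaults with one logged warning.
* Exit codes: 0 success, 2 usage, 3 input validation, 4 numerical failure.

## Known limitations

* The energy model omits mismatch/dangle/coaxial terms and uses toy
  tables; absolute energies and probabilities are not comparable to
  Turner-parameter implementations.
* The expected-partition DP is exact but dense: `O(n^3)`-ish time with a
  large constant; the package targets hundreds of nucleotides on a CPU,
  not genome-scale screens.
* Base-pair probability matrices, minimum-free-energy structures,
  suboptimal sampling, and pseudoknots are out of scope.
* The CAI repair projection is greedy and minimizes marginal-probability
  loss per swap; it does not search the feasible set for the EFE-optimal
  repair.
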