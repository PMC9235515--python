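# Methods

`alnzone` quantifies how much a pairwise protein sequence alignment can be
trusted, and at what divergence residue–residue correspondences from
sequence alone stop being meaningful.  This note records the statistical
model, the algorithms, the numerical choices, and the places where the
design was genuinely open.

## The generative model being scored

A pairwise alignment of amino-acid sequences S and T is treated as a
hypothesis about their residue-level relationship, scored by the total
length in bits of a lossless two-part encoding (minimum message length):

    I(A, <S,T>) = I(A) + I(<S,T> | A) = -log2 Pr(A, <S,T>).

**First part — the alignment.**  The three-state string of A over
{match, insert, delete} is priced by a Markov-time-parameterized
finite-state machine.  The machine's transition matrix T(t) carries a
constant per-step stop mass ρ (each row sums to 1−ρ), so the alignment
message is self-delimiting and no separate length code is needed for it.

**Second part — the residues.**  Matched columns are priced by the joint
interchange probability π[a]·(M^t)[a,b] of a time-parameterized
substitution model (base stochastic matrix M, stationary distribution π);
inserted and deleted residues by the time-independent 20-nomial
background, which defaults to π.

**Null model.**  NULL(<S,T>) = NULL(S) + NULL(T); each sequence costs a
log-star universal integer code for its length (normalizer 2.865064) plus
the 20-nomial cost of its residues.  A hypothesis is accepted only if it
compresses better than the null (Δ = NULL − I > 0; Δ = 0 rejects).  The
cost of stating the Markov time t is charged in neither message; the Δ
statistics are therefore internally consistent, but their absolute values
are specific to this package's codes and are not interchangeable with
other implementations of the same idea.

**Marginal relatedness.**  Summing Pr(A, <S,T>) over all alignments gives
the marginal probability that the pair is related at time t, computed by
a forward dynamic program over three per-state matrices in natural-log
space with log-sum-exp (unscaled linear space underflows beyond ~100
residues).  Minimizing I_marginal over t yields the unbiased divergence
estimate time_marginal; minimizing the optimal two-part length yields the
biased time_optimal.

## The alignment machine: reversibility as a design constraint

The exact time-dependence of the three-state machine's transitions is the
one genuinely under-specified component of the framework, so it sits
behind a small interface (`AlignmentMachine`), and the default is an
explicit stand-in with two properties chosen deliberately:

1. **Smooth monotone time-dependence.**  Match-state occupancy
   μ(t) = 0.55 + 0.40·exp(−t/300) decays toward a floor; the gap-open
   probability g(t) = 0.01 + 0.04·(1 − exp(−t/200)) rises toward a
   ceiling.  Saturating exponentials were used rather than logistics:
   same qualitative role, simpler algebra under the reversibility
   constraint below.  All four coefficients, the timescales, the
   insert↔delete cross probability (0.05) and the stop mass
   (ρ = 0.002, mean alignment length 500 columns — typical domain scale)
   live in `MachineParameters`.

2. **Detailed balance, begun at stationarity.**  Transitions satisfy
   π_state[x]·T[x→y] = π_state[y]·T[y→x] with stationary occupancy
   (μ, (1−μ)/2, (1−μ)/2), and that occupancy is also the begin-state
   distribution.  Consequence: the probability of every alignment — and
   hence the marginal — is *exactly* invariant under reversing both
   sequences.  This is what makes the landscape construction (below)
   internally consistent to machine precision rather than approximately.
   The more common convention of treating the begin state as a match
   would break this identity, which is why it was not used.  The
   gap-close probability is then forced to 2gμ/(1−μ) by detailed
   balance rather than being a free parameter.

Because the bundled substitution models are also reversible (detailed
balance of π against M), swapping S and T likewise leaves the marginal
unchanged.

## Bundled substitution models

The four bundled matrices (`pam-like`, `blosum-like`, `vtml-like`,
`mmlsum-like`) are **synthetic stand-ins**, not the published PAM, BLOSUM,
VTML or MMLSUM derivations: each is a reversible GTR-style chain on
average amino-acid background frequencies with seeded lognormal
exchangeabilities, rate-scaled so that the expected %-change of amino
acids, 100·(1 − Σ_a π[a]·(M^t)[a,a]), reaches a per-model calibration
point at t = 150 (70.5% for `mmlsum-like`, the daylight-zone boundary
value) and ~92–94% by t ≈ 500.  They are generated deterministically by
`scripts/make_substitution_models.py` and shipped as plain text (symbol
order, 20 conditional rows, stationary row).  Fractional matrix powers
use the eigendecomposition of the base matrix; reversibility guarantees
real positive eigenvalues, and round-off entries above −1e−12 are clamped
and rows renormalized.  Reversibility also makes the expected %-change
provably non-decreasing in t (the π-weighted trace of M^t is a
non-negative mixture of λ_i^t with λ_i ∈ (0, 1]).

**Residue policy.**  Strict mode accepts only the 20 canonical letters.
Lenient mode (default) maps B→D, Z→E, U→C and treats X as an averaged
pseudo-residue whose encoding cost is the stationary-weighted mean
log-cost — the expected cost of a residue drawn from the background.

## Inter-alignment distance

An alignment is a monotone source-to-sink lattice path.  Every path
crosses each skew diagonal k = i+j exactly once; recording the proper
diagonal j−i at each crossing gives the path's diagonal profile π_k, and

    distance(A1, A2) = Σ_k |π1(k) − π2(k)|

is the summed width between the paths — an L1 metric on profiles that
grades near-misses instead of scoring columns as identical or not.  A
diagonal (match) move crosses two skew diagonals at its constant proper
diagonal; this two-crossing bookkeeping is forced on the expected-distance
recurrence below.  The normalized distance divides by |S|+|T|, the
maximum alignment length; the worst case is the corner-hugging path pair
at raw distance exactly 2·|S|·|T|.

## Expected distance to a reference alignment

Rather than comparing one (biased) optimal sequence alignment against a
structure-derived reference A_ref, the package computes the exact
posterior expectation

    E[distance(A, A_ref)] = Σ_A Pr(A | <S,T>) · distance(A, A_ref),

with Pr(A | <S,T>) = Pr(A, <S,T>) / Pr_marginal(<S,T>), by a three-matrix
dynamic program in O(|S||T|) time and space.  EADm/EADi/EADd(i, j) hold
the expected-distance mass of all prefix alignments ending at (i, j) in
each state, weighted by unnormalized joint probability.  Each cell
propagates predecessor mass through the transition and emission terms and
adds the per-state component marginal at (i, j) times the new width
element(s): one δ term for insert/delete arrivals, two (skews i+j−1 and
i+j) for match arrivals.  The widths δ are O(1) lookups against the
reference profile.  Termination sums the three corner cells and divides
by the marginal; dividing further by |S|+|T| gives the normalized value.

**Numerics.**  Expectations mix signed-weighted mass with probabilities,
so this pass runs in *linear* space with per-anti-diagonal rescaling: each
anti-diagonal is divided by its largest forward mass, the cumulative log
factor is tracked, and contributions reaching back two anti-diagonals
(diagonal moves, and the begin cell at anti-diagonal 2) are brought into
the working scale explicitly.  The final ratio cancels all factors.  A
150×150 pair at t = 200 stays finite; the log-space forward pass and the
linear-space pass agree through the enumeration oracle.

**Per-diagonal profile.**  The expected width per skew diagonal is also
computed by a *different* algorithm — forward–backward posteriors of each
move — and must sum to the DP's raw expectation (used as an internal
cross-check and a diagnostic for locating disagreement).

**Validation.**  Both DPs and the distance are validated against full
enumeration (the alignment count Σ_L L!/((L−m)!(L−n)!(m+n−L)!) is 13 at
2×2, 1683 at 5×5) to 1e−9 relative on hundreds of random small pairs, and
against Monte-Carlo sampling: alignments drawn by backward stochastic
traceback from the per-state forward matrices are distributed exactly as
the posterior (chi-square-checked on enumerable instances), and the
1000-sample empirical mean distance brackets the exact value within
sampling error.

## Divergence zones

time_marginal partitions pairs into zones: daylight (t ≤ 150 — sequence
and structure alignments agree closely), twilight (150 < t ≤ 250 —
correspondences become unreliable), midnight (250 < t ≤ 350 — sequence
alignments should be ignored) and beyond (t > 350 — past the limit of
inference).  Zone boundaries are inclusive on the lower zone (a
convention; the source ranges overlap at the boundaries) and configurable
via `ZoneThresholds`.  Pairs are also grouped by compression statistics:
group1 (Δ_optimal > 0), group2 (Δ_optimal ≤ 0 < Δ_marginal), group3
(Δ_marginal ≤ 0).  Survey summaries bin pairs by integer time_marginal
and report per-bin quartiles (linear-interpolation convention) of the
normalized expected distance plus cumulative pair percentage.

## Time inference

time estimates minimize the corresponding message length over
t ∈ [1, 500] (the range whose expected %-change spans ~1%–92%): a coarse
integer grid of stride 8 locates the basin, then bounded golden-section
search (tolerance 1e−3) refines it.  The stride is a deliberate
cost/resolution trade-off; objectives for the bundled models are smooth
and unimodal in practice, and the refined optimum is accepted only if it
does not exceed the best grid value.  Flat objectives return the lower
bound (documented tie-break).  Optimal-DP traceback breaks exact ties
preferring match over delete over insert.

## Synthetic pairs and what passing tests show

`simulate.evolve_pair` draws the machine's state string at the true time
(stop mass renormalized away, extension until both sequences reach the
target length), fills matched columns from the joint interchange
distribution (ancestor from π — stationarity makes the expected %-change
exact for matched columns) and gap columns from the background.
Generation and inference share one model, so recovery experiments certify
the *inference machinery*: with ancestor length 200 and 50 replicates,
median recovered time_marginal lands within ±15% of truth at t = 50, 150
and 250, and the median normalized expected distance to the true
alignment rises strictly with divergence — the synthetic analogue of the
survey trend.  They do **not** certify realism: the generator has no
structural constraints, no site-rate variation, no empirical indel length
distribution (gap geometry is geometric, from the machine's
self-transitions), and its gap-close rate is tied to gap-open by
reversibility.

## Problem sizes and defaults used in the shipped experiments

Oracle-equivalence checks: 200 random pairs with lengths ≤ 5 over the
full time range.  Sampler checks: 100 000 draws on 1×1 and 2×2 pairs,
1000-draw empirical means on 20 random small pairs.  Recovery: 3 true
times × 50 replicates × length 200.  These sizes were chosen as the
smallest that make the statistical assertions sharp; all are
seed-reproducible.

## Known limitations

- The machine's transition parameterization and the substitution matrices
  are this package's own calibrated stand-ins; absolute bit values and
  inferred times are therefore not comparable against other
  implementations, although all internal identities and trends are.
- Expected distance is always taken to a single fixed reference
  alignment, not between two alignment distributions.
- Only pairwise comparison is supported — no database search heuristics,
  and no structure handling (reference alignments are consumed as gapped
  FASTA produced by external structure-alignment tools).
- The landscape is the product of standalone prefix and suffix marginals,
  a visualization surface: cell values are bounded below by I_marginal
  and equal it at the corners, but interior cells are not per-cell
  posteriors.
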