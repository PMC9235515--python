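# alnzone

**How reliable is a pairwise protein sequence alignment — and at what
divergence should you stop believing it?**

A single "optimal" sequence alignment is one hypothesis among a
factorially large set, and as two proteins diverge, the posterior mass
spreads over many alternatives that a structure-based alignment may
contradict.  `alnzone` quantifies this directly: it scores alignments as
lossless two-part codes under the minimum message length (MML) criterion,
marginalizes over *all* alignments to decide whether two sequences are
related at all, infers the Markov divergence time automatically, and
computes — exactly, in O(|S||T|) — the posterior-expected distance
between the set of all sequence alignments and a fixed reference
(typically structure-derived) alignment.  The inferred time places each
pair in the **daylight** (t ≤ 150), **twilight** (150 < t ≤ 250),
**midnight** (250 < t ≤ 350) or **beyond** (t > 350) zone of sequence
relationships.

## The statistics it computes

For a pair ⟨S, T⟩, an alignment A (a three-state string over
match/insert/delete) is scored as

    I(A, ⟨S,T⟩) = I(A) + I(⟨S,T⟩ | A)   bits,

with the state string priced by a time-parameterized three-state machine
and residues priced by a time-parameterized substitution model
(matched columns: π[a]·(M^t)[a,b]; gaps: the 20-nomial background).
Marginalizing,

    I_marginal(⟨S,T⟩) = −log2 Σ_A Pr(A, ⟨S,T⟩),

and both quantities are minimized over t to give time_optimal (biased)
and time_marginal (unbiased).  Compression against the null encoding,
Δ = NULL(⟨S,T⟩) − I, is the significance test (Δ > 0 accepts).

The distance between two alignments is the summed width between their
lattice paths over all skew diagonals k = i + j,

    distance(A1, A2) = Σ_k |π1(k) − π2(k)|,

where π(k) is the proper diagonal j − i at which a path crosses skew
diagonal k.  The headline quantity is its exact posterior expectation
against a reference alignment,

    E[distance(A, A_ref)] = Σ_A Pr(A | ⟨S,T⟩) · distance(A, A_ref),

computed by a three-matrix dynamic program (validated against exhaustive
enumeration and against Monte-Carlo alignment sampling), and normalized
by |S| + |T|.

See `docs/methods.md` for the model, the recurrences, numerical choices,
and the package's own calibration decisions (the bundled substitution
matrices are synthetic, reversible stand-ins calibrated so the
`mmlsum-like` model reaches 70.5% expected amino-acid change at t = 150).

## Worked example

Simulate a related pair of ~120-residue sequences at a known divergence
(Markov time 150), then compare them from sequence alone:

    $ alnzone simulate --length 120 --time 150 --seed 11 --out demo
    $ alnzone compare --pair demo/pair_t150_r0.fasta
    pair        sim11_S|sim11_T
    null_bits   1034.2
    i_optimal_bits      972.6
    i_marginal_bits     969.2
    delta_optimal       61.7
    delta_marginal      65.1
    time_optimal        143.0
    time_marginal       140.0
    zone        daylight
    group       group1
    optimal_significant True
    marginal_significant        True

Both the single best alignment and the marginal beat the null by ~62–65
bits, so the relationship is significant (group1), and the inferred
unbiased time 140 recovers the true divergence 150 to within 7%, landing
in the daylight zone.  Now score the full posterior against the true
(generating) alignment, exactly and by sampling:

    $ alnzone ead --pair demo/pair_t150_r0.fasta --ref demo/pair_t150_r0.ref.fasta
    raw     normalized      time    i_marginal_bits
    63.714  0.262   140.0   969.2

    $ alnzone sample --pair demo/pair_t150_r0.fasta --ref demo/pair_t150_r0.ref.fasta --n 1000 --seed 42
    mean    se      n       seed
    0.2608  0.0060  1000    42

The exact expected distance per alignment column is 0.262; the empirical
estimate from 1000 posterior-sampled alignments, 0.261 ± 0.006, confirms
it.  Near the daylight boundary the typical sequence alignment already
wanders about a quarter of a column away from the truth, on average —
small, but no longer negligible; in the midnight zone this statistic
grows by an order of magnitude.

Other subcommands: `landscape` (marginal probability landscape export),
`zones` (quartile-versus-time survey summaries), `classify`, `recover`
(divergence-time recovery experiments on simulated pairs).  Everything is
also available as a library (`import alnzone`).

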