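"""Stochastic traceback sampling of alignments from the marginal matrices.

Alignments are drawn with probability exactly equal to their posterior
Pr(A | <S,T>): starting from the sink cell with the end state drawn in
proportion to the per-state forward mass, each predecessor state is drawn
in proportion to its forward mass times the connecting transition
probability (emissions at the current cell are common to all predecessors
and cancel).  Averaging the distances of sampled alignments to a reference
gives an empirical estimate of the expected inter-alignment distance, used
to validate the exact dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .align_distance import Alignment, alignment_distance, normalized_distance
from .errors import InferenceError
from .mml_core import (
    LOG2,
    ForwardMatrices,
    SequencePair,
    _machine_logs,
    forward_matrices,
    marginal_compare,
)
from .models import AlignmentMachine, SubstitutionModel

__all__ = ["SampleSet", "sample_alignment", "sample_alignments",
           "empirical_expected_distance"]


@dataclass
class SampleSet:
    """Alignments sampled from the posterior, with provenance."""

    alignments: list[Alignment]
    seed: int
    t: float

    @property
    def size(self) -> int:
        return len(self.alignments)


def _draw(rng: np.random.Generator, log_weights: np.ndarray) -> int:
    mx = log_weights.max()
    if mx == -np.inf:
        raise InferenceError("degenerate forward matrices: no mass to sample")
    w = np.exp(log_weights - mx)
    w /= w.sum()
    return int(rng.choice(len(w), p=w))


def sample_alignment(forward: ForwardMatrices, machine: AlignmentMachine,
                     rng: np.random.Generator) -> Alignment:
    """Draw one alignment with probability Pr(A | <S,T>) by backward
    stochastic traceback over the per-state forward matrices."""
    Fm = -forward.fm * LOG2
    Fi = -forward.fi * LOG2
    Fd = -forward.fd * LOG2
    lt, _, _ = _machine_logs(machine, forward.t)
    m, n = Fm.shape[0] - 1, Fm.shape[1] - 1
    F = (Fm, Fi, Fd)

    state = _draw(rng, np.array([Fm[m, n], Fi[m, n], Fd[m, n]]))
    i, j = m, n
    states = []
    while True:
        states.append("mid"[state])
        if state == 0:
            pi_, pj_ = i - 1, j - 1
        elif state == 1:
            pi_, pj_ = i - 1, j
        else:
            pi_, pj_ = i, j - 1
        if (pi_, pj_) == (0, 0):
            break
        lw = np.array([F[y][pi_, pj_] + lt[y, state] for y in range(3)])
        state = _draw(rng, lw)
        i, j = pi_, pj_
    return Alignment("".join(reversed(states)))


def sample_alignments(pair: SequencePair, model: SubstitutionModel,
                      machine: AlignmentMachine, n: int, seed: int,
                      t: float | None = None) -> SampleSet:
    """Draw ``n`` posterior alignment samples (reproducible given seed).

    ``t`` defaults to the inferred unbiased Markov time.
    """
    if n < 1:
        raise ValueError("sample count must be at least 1")
    if t is None:
        marg, fwd = marginal_compare(pair, model, machine)
        t = marg.time_marginal
    else:
        fwd = forward_matrices(pair, model, machine, t)
    rng = np.random.default_rng(seed)
    alignments = [sample_alignment(fwd, machine, rng) for _ in range(n)]
    return SampleSet(alignments, seed, float(t))


def empirical_expected_distance(pair: SequencePair, a_ref: Alignment,
                                model: SubstitutionModel,
                                machine: AlignmentMachine, n: int, seed: int,
                                t: float | None = None) -> tuple[float, float]:
    """Monte-Carlo estimate of the normalized expected distance to
    ``a_ref``: mean over ``n`` posterior samples, with its standard error."""
    m_len, n_len = pair.shape
    a_ref.require_pair(m_len, n_len)
    samples = sample_alignments(pair, model, machine, n, seed, t=t)
    dists = np.array(
        [normalized_distance(alignment_distance(a, a_ref), m_len, n_len)
         for a in samples.alignments]
    )
    mean = float(dists.mean())
    se = float(dists.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, se
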