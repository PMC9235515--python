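"""Exact posterior-weighted expected distance of all sequence alignments
to a fixed reference alignment.

The expectation  E[distance(A, A_ref)] = sum_A Pr(A | <S,T>) distance(A, A_ref)
runs over a factorially large alignment set, but decomposes over skew
diagonals: every alignment path crosses each skew diagonal exactly once,
and the distance is the summed width between path and reference at each
crossing.  Three memoization matrices EADm/EADi/EADd — expected-distance
mass weighted by unnormalized joint probability, per ending state — admit
a bottom-up recurrence over cells: transitions and emissions propagate
accumulated mass, and each cell adds its component marginal probability
times the new width element(s).  A match move crosses two skew diagonals,
so it adds two width terms; insert and delete moves add one.  Summing the
three corner cells and dividing by the marginal probability yields the
expectation in O(|S||T|) time and space.

Accumulation is done in linear space with per-anti-diagonal rescaling
(expectations mix probability mass with distance weights, which log-space
cannot represent; unscaled linear space underflows for long sequences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .align_distance import Alignment, diagonal_profile, normalized_distance
from .errors import InferenceError
from .mml_core import (
    LOG2,
    SequencePair,
    _emissions,
    _machine_logs,
    backward_matrices,
    forward_matrices,
    marginal_compare,
)
from .models import AlignmentMachine, SubstitutionModel

__all__ = [
    "EadResult",
    "EadMatrices",
    "expected_alignment_distance",
    "expected_distance_profile",
]


@dataclass
class EadResult:
    """Expected inter-alignment distance at one Markov time."""

    raw: float
    normalized: float
    t: float
    i_marginal_bits: float


@dataclass
class EadMatrices:
    """The three expected-distance-mass matrices plus the per-state forward
    (component-marginal) matrices, rescaled per anti-diagonal.

    ``scale_log[k]`` is the cumulative natural-log rescaling applied to
    anti-diagonal ``k``; true values are ``stored * exp(scale_log[k])``.
    """

    ead_m: np.ndarray
    ead_i: np.ndarray
    ead_d: np.ndarray
    g_m: np.ndarray
    g_i: np.ndarray
    g_d: np.ndarray
    scale_log: np.ndarray


def _reference_pi(a_ref: Alignment, m: int, n: int) -> np.ndarray:
    a_ref.require_pair(m, n)
    return diagonal_profile(a_ref).pi.astype(float)


def _ead_pass(pair: SequencePair, a_ref: Alignment, model: SubstitutionModel,
              machine: AlignmentMachine, t: float) -> tuple[float, EadMatrices]:
    m, n = pair.shape
    pi_ref = _reference_pi(a_ref, m, n)
    ej, lbs, lbt = _emissions(pair, model, t)
    lt, lbeg, _ = _machine_logs(machine, t)
    T = np.exp(lt)
    beg = np.exp(lbeg)
    Pj = np.exp(ej)          # match joint emissions, m x n
    Ps = np.exp(lbs)         # S background, length m
    Pt = np.exp(lbt)         # T background, length n

    shape = (m + 1, n + 1)
    Gm, Gi, Gd = (np.zeros(shape) for _ in range(3))
    Em, Ei, Ed = (np.zeros(shape) for _ in range(3))
    scale_log = np.zeros(m + n + 1)

    size = m + 1
    zero = np.zeros(size)
    gm2, gi2, gd2 = zero.copy(), zero.copy(), zero.copy()
    em2, ei2, ed2 = zero.copy(), zero.copy(), zero.copy()
    gm1, gi1, gd1 = zero.copy(), zero.copy(), zero.copy()
    em1, ei1, ed1 = zero.copy(), zero.copy(), zero.copy()
    prev_rescale = 1.0  # exp(scale_log[k-2] - scale_log[k-1])

    for k in range(1, m + n + 1):
        lo, hi = max(0, k - n), min(m, k)
        iarr = np.arange(lo, hi + 1)
        jarr = k - iarr
        cgm, cgi, cgd = zero.copy(), zero.copy(), zero.copy()
        cem, cei, ced = zero.copy(), zero.copy(), zero.copy()

        # widths at this skew diagonal for each cell's proper diagonal
        diag = (jarr - iarr).astype(float)
        d_here = np.abs(diag - pi_ref[k])
        d_prev = np.abs(diag - pi_ref[k - 1])  # second width of a match move

        # match into (i, k-i) from anti-diagonal k-2 at i-1
        msk = (iarr >= 1) & (jarr >= 1)
        if msk.any():
            ii = iarr[msk]
            e = Pj[ii - 1, k - ii - 1]
            pred_g = (gm2[ii - 1] * T[0, 0] + gi2[ii - 1] * T[1, 0]
                      + gd2[ii - 1] * T[2, 0]) * prev_rescale
            pred_e = (em2[ii - 1] * T[0, 0] + ei2[ii - 1] * T[1, 0]
                      + ed2[ii - 1] * T[2, 0]) * prev_rescale
            cgm[ii] = pred_g * e
            cem[ii] = pred_e * e
        # insert into (i, k-i) from anti-diagonal k-1 at i-1
        msk = iarr >= 1
        if msk.any():
            ii = iarr[msk]
            e = Ps[ii - 1]
            cgi[ii] = (gm1[ii - 1] * T[0, 1] + gi1[ii - 1] * T[1, 1]
                       + gd1[ii - 1] * T[2, 1]) * e
            cei[ii] = (em1[ii - 1] * T[0, 1] + ei1[ii - 1] * T[1, 1]
                       + ed1[ii - 1] * T[2, 1]) * e
        # delete into (i, k-i) from anti-diagonal k-1 at i
        msk = jarr >= 1
        if msk.any():
            ii = iarr[msk]
            e = Pt[k - ii - 1]
            cgd[ii] = (gm1[ii] * T[0, 2] + gi1[ii] * T[1, 2]
                       + gd1[ii] * T[2, 2]) * e
            ced[ii] = (em1[ii] * T[0, 2] + ei1[ii] * T[1, 2]
                       + ed1[ii] * T[2, 2]) * e

        # begin contributions (predecessor is the source cell)
        if k == 1:
            if m >= 1:
                cgi[1] = beg[1] * Ps[0]
                cei[1] = 0.0
            if n >= 1:
                cgd[0] = beg[2] * Pt[0]
                ced[0] = 0.0
        elif k == 2 and m >= 1 and n >= 1:
            # absolute probability, brought into the working scale of
            # anti-diagonal k-1 like the other diagonal-move predecessors
            cgm[1] = beg[0] * Pj[0, 0] * prev_rescale
            cem[1] = 0.0

        # add the new width mass: component marginal at the cell times the
        # width element(s) the arriving move crosses
        full = np.zeros(size)
        full[iarr] = d_here
        fprev = np.zeros(size)
        fprev[iarr] = d_prev
        cem += cgm * (fprev + full)   # match move covers skews k-1 and k
        cei += cgi * full
        ced += cgd * full

        # rescale this anti-diagonal by its largest forward mass
        mass = max(cgm.max(), cgi.max(), cgd.max())
        if mass <= 0.0:
            raise InferenceError(
                f"all alignment mass vanished on anti-diagonal {k}"
            )
        for arr in (cgm, cgi, cgd, cem, cei, ced):
            arr /= mass
        scale_log[k] = scale_log[k - 1] + math.log(mass)
        prev_rescale = 1.0 / mass

        Gm[iarr, jarr] = cgm[iarr]; Gi[iarr, jarr] = cgi[iarr]; Gd[iarr, jarr] = cgd[iarr]
        Em[iarr, jarr] = cem[iarr]; Ei[iarr, jarr] = cei[iarr]; Ed[iarr, jarr] = ced[iarr]

        gm2, gi2, gd2, em2, ei2, ed2 = gm1, gi1, gd1, em1, ei1, ed1
        gm1, gi1, gd1, em1, ei1, ed1 = cgm, cgi, cgd, cem, cei, ced

    g_total = gm1[m] + gi1[m] + gd1[m]
    e_total = em1[m] + ei1[m] + ed1[m]
    raw = e_total / g_total  # stop factor and cumulative scale cancel
    mats = EadMatrices(Em, Ei, Ed, Gm, Gi, Gd, scale_log)
    return raw, mats


def expected_alignment_distance(
    pair: SequencePair,
    a_ref: Alignment,
    model: SubstitutionModel,
    machine: AlignmentMachine,
    t: float | None = None,
    return_matrices: bool = False,
):
    """Expected distance of all sequence alignments to ``a_ref``.

    ``t`` defaults to the inferred unbiased Markov time (time_marginal).
    Returns an :class:`EadResult` with the raw expectation and the
    length-normalized expectation (divided by ``|S| + |T|``), or
    ``(result, EadMatrices)`` when ``return_matrices`` is set.
    """
    m, n = pair.shape
    a_ref.require_pair(m, n)
    if t is None:
        marg, _ = marginal_compare(pair, model, machine)
        t = marg.time_marginal
        i_marg = marg.i_marginal_bits
    else:
        from .mml_core import marginal_bits
        i_marg = marginal_bits(pair, model, machine, t)
    raw, mats = _ead_pass(pair, a_ref, model, machine, t)
    result = EadResult(
        raw=float(raw),
        normalized=normalized_distance(float(raw), m, n),
        t=float(t),
        i_marginal_bits=float(i_marg),
    )
    if return_matrices:
        return result, mats
    return result


def expected_distance_profile(
    pair: SequencePair,
    a_ref: Alignment,
    model: SubstitutionModel,
    machine: AlignmentMachine,
    t: float | None = None,
) -> np.ndarray:
    """Per-skew-diagonal decomposition of the expected distance.

    Entry ``k`` is the posterior-expected width between sequence
    alignments and the reference at skew diagonal ``k``; the vector sums
    to the raw expectation.  Computed by forward-backward posterior moves
    (an algorithm independent of the three-matrix recurrence), which makes
    it a useful internal cross-check as well as a diagnostic for locating
    where sequence and reference alignments disagree.
    """
    m, n = pair.shape
    a_ref.require_pair(m, n)
    if t is None:
        marg, _ = marginal_compare(pair, model, machine)
        t = marg.time_marginal
    pi_ref = _reference_pi(a_ref, m, n)
    fwd = forward_matrices(pair, model, machine, t)
    Bm, Bi, Bd = backward_matrices(pair, model, machine, t)
    # forward matrices in nats (they are stored as bits)
    Fm, Fi, Fd = (-fwd.fm * LOG2, -fwd.fi * LOG2, -fwd.fd * LOG2)
    z = fwd.total_bits() - math.log2(machine.stop)  # I_marginal in bits
    z_nats = -z * LOG2
    with np.errstate(invalid="ignore"):
        post_m = np.exp(Fm + Bm - z_nats)
        post_i = np.exp(Fi + Bi - z_nats)
        post_d = np.exp(Fd + Bd - z_nats)
    for p in (post_m, post_i, post_d):
        np.nan_to_num(p, copy=False)

    profile = np.zeros(m + n + 1)
    ii, jj = np.indices((m + 1, n + 1))
    kk = ii + jj
    diag = (jj - ii).astype(float)
    width_here = np.abs(diag - pi_ref[kk])
    valid = kk >= 1
    np.add.at(profile, kk[valid], (post_i + post_d)[valid] * width_here[valid])
    # a match move into (i, j) covers skew diagonals i+j-1 and i+j
    np.add.at(profile, kk[valid], post_m[valid] * width_here[valid])
    kprev = np.maximum(kk - 1, 0)
    width_prev = np.abs(diag - pi_ref[kprev])
    valid2 = kk >= 2
    np.add.at(profile, kprev[valid2], post_m[valid2] * width_prev[valid2])
    return profile
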