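"""Two-part message lengths, marginal and optimal alignment dynamic
programs, and Markov-time inference.

Under the minimum-message-length view, an alignment ``A`` of sequences
``<S, T>`` is a hypothesis whose merit is the total length (in bits) of a
lossless two-part encoding: the alignment's three-state string priced by
the time-parameterized alignment machine (first part), plus the residues
priced by the substitution model through the alignment (matched columns
from the joint interchange probabilities at Markov time ``t``, gapped
residues from the 20-nomial background).  The null message encodes both
sequences independently; an alignment whose message does not beat the null
is rejected.

Marginalizing the joint probability over *all* alignments gives the
marginal probability that the pair is related, computed by a forward
dynamic program over three per-state matrices in log space.  Minimizing
the optimal or marginal message length over ``t`` yields the biased
(optimal) and unbiased (marginal) divergence-time estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

from .align_distance import Alignment
from .errors import InferenceError, ModelError
from .models import ALPHABET, AlignmentMachine, SubstitutionModel

__all__ = [
    "SequencePair",
    "ComparisonResult",
    "ForwardMatrices",
    "Landscape",
    "LOG2",
    "log_star",
    "null_length",
    "count_alignments",
    "infer_time",
    "marginal_bits",
    "forward_matrices",
    "backward_matrices",
    "alignment_length",
    "optimal_compare",
    "marginal_compare",
    "compare_pair",
    "landscape",
    "significance",
]

LOG2 = math.log(2.0)
_NEG_INF = -np.inf

#: normalizer of the log-star universal code over positive integers,
#: sum over n>=1 of 2^-logstar(n) = 1 with this constant
_LOG_STAR_C = 2.865064


@dataclass(frozen=True)
class SequencePair:
    """A validated pair of amino-acid sequences.

    Residues are resolved by the alphabet policy at construction
    (``lenient`` maps B/Z/U to D/E/C and X to the averaged pseudo-residue;
    ``strict`` rejects all of them).
    """

    s: str
    t: str
    s_id: str = "S"
    t_id: str = "T"
    policy: str = "lenient"

    def __post_init__(self):
        if not self.s or not self.t:
            raise ValueError("sequences must be non-empty")
        object.__setattr__(self, "s_idx", ALPHABET.encode(self.s, self.policy))
        object.__setattr__(self, "t_idx", ALPHABET.encode(self.t, self.policy))

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.s), len(self.t)

    def reversed(self) -> "SequencePair":
        return SequencePair(self.s[::-1], self.t[::-1],
                            self.s_id + "_rev", self.t_id + "_rev", self.policy)

    def swapped(self) -> "SequencePair":
        return SequencePair(self.t, self.s, self.t_id, self.s_id, self.policy)


@dataclass
class ComparisonResult:
    """Message-length statistics of a pairwise comparison (bits)."""

    null_bits: float
    i_optimal_bits: float | None = None
    i_marginal_bits: float | None = None
    time_optimal: float | None = None
    time_marginal: float | None = None
    optimal_alignment: Alignment | None = None

    @property
    def delta_optimal_bits(self) -> float | None:
        if self.i_optimal_bits is None:
            return None
        return self.null_bits - self.i_optimal_bits

    @property
    def delta_marginal_bits(self) -> float | None:
        if self.i_marginal_bits is None:
            return None
        return self.null_bits - self.i_marginal_bits


@dataclass
class ForwardMatrices:
    """Per-state forward matrices in bits.

    Cell (i, j) of ``fm``/``fi``/``fd`` holds the negative base-2 log of
    the summed joint probability of all alignments of the prefixes
    ``S[1..i], T[1..j]`` ending at (i, j) in the match/insert/delete state
    (without the terminal stop factor).  Combining the three corner cells
    with the stop probability reproduces ``I_marginal``.
    """

    fm: np.ndarray
    fi: np.ndarray
    fd: np.ndarray
    t: float

    def total_bits(self) -> float:
        return _combine_bits(self.fm[-1, -1], self.fi[-1, -1], self.fd[-1, -1])


@dataclass
class Landscape:
    """Negative log of prefix-marginal times suffix-marginal, per cell."""

    matrix: np.ndarray
    t: float
    i_marginal_bits: float


def _combine_bits(*bits: float) -> float:
    nats = [-b * LOG2 for b in bits]
    m = max(nats)
    if m == _NEG_INF:
        return np.inf
    return -(m + math.log(sum(math.exp(x - m) for x in nats))) / LOG2


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def log_star(n: int) -> float:
    """Universal (log-star) code length in bits for a positive integer."""
    if n < 1:
        raise ValueError(f"log-star code is defined for n >= 1, got {n}")
    length = math.log2(_LOG_STAR_C)
    x = float(n)
    while True:
        x = math.log2(x)
        if x <= 0:
            break
        length += x
    return length


def null_length(pair: SequencePair, model: SubstitutionModel) -> float:
    """NULL(<S,T>) = NULL(S) + NULL(T): for each sequence, a log-star code
    of its length plus the 20-nomial cost of its residues."""
    lb = model.log_background()
    bits_s = log_star(len(pair.s)) - lb[pair.s_idx].sum() / LOG2
    bits_t = log_star(len(pair.t)) - lb[pair.t_idx].sum() / LOG2
    return bits_s + bits_t


# ---------------------------------------------------------------------------
# alignment counting
# ---------------------------------------------------------------------------

def count_alignments(m: int, n: int) -> int:
    """Number of distinct alignments of sequences of lengths m and n:
    sum over alignment lengths L of L! / ((L-m)! (L-n)! (m+n-L)!)."""
    if m < 0 or n < 0:
        raise ValueError("sequence lengths must be non-negative")
    total = 0
    for L in range(max(m, n), m + n + 1):
        total += math.factorial(L) // (
            math.factorial(L - m) * math.factorial(L - n) * math.factorial(m + n - L)
        )
    return total


# ---------------------------------------------------------------------------
# shared DP scaffolding
# ---------------------------------------------------------------------------

def _emissions(pair: SequencePair, model: SubstitutionModel, t: float):
    """Natural-log emission tables: match joint (m x n), S and T background."""
    lj = model.log_joint(t)
    lb = model.log_background()
    ej = lj[np.ix_(pair.s_idx, pair.t_idx)]
    return ej, lb[pair.s_idx], lb[pair.t_idx]


def _machine_logs(machine: AlignmentMachine, t: float):
    with np.errstate(divide="ignore"):
        lt = np.log(machine.transition(t))
        lbeg = np.log(machine.begin(t))
    return lt, lbeg, math.log(machine.stop)


def _forward_pass(pair, model, machine, t, keep: bool):
    """Anti-diagonal forward DP in natural-log space.

    Returns (total_nats, full per-state nat matrices or None).  ``keep``
    stores the full (m+1)x(n+1) matrices; otherwise only three rolling
    anti-diagonals are held.
    """
    m, n = pair.shape
    ej, lbs, lbt = _emissions(pair, model, t)
    lt, lbeg, lstop = _machine_logs(machine, t)

    if keep:
        Fm = np.full((m + 1, n + 1), _NEG_INF)
        Fi = np.full((m + 1, n + 1), _NEG_INF)
        Fd = np.full((m + 1, n + 1), _NEG_INF)

    neg = np.full(m + 1, _NEG_INF)
    pm2, pi2, pd2 = neg.copy(), neg.copy(), neg.copy()   # diag k-2
    pm1, pi1, pd1 = neg.copy(), neg.copy(), neg.copy()   # diag k-1

    for k in range(1, m + n + 1):
        lo, hi = max(0, k - n), min(m, k)
        iarr = np.arange(lo, hi + 1)
        cm, ci, cd = neg.copy(), neg.copy(), neg.copy()

        # match into (i, k-i): predecessors on diag k-2 at i-1
        msk = (iarr >= 1) & (k - iarr >= 1)
        if msk.any():
            ii = iarr[msk]
            pred = np.logaddexp(
                np.logaddexp(pm2[ii - 1] + lt[0, 0], pi2[ii - 1] + lt[1, 0]),
                pd2[ii - 1] + lt[2, 0],
            )
            cm[ii] = pred + ej[ii - 1, k - ii - 1]
        # insert (consumes S): predecessors on diag k-1 at i-1
        msk = iarr >= 1
        if msk.any():
            ii = iarr[msk]
            pred = np.logaddexp(
                np.logaddexp(pm1[ii - 1] + lt[0, 1], pi1[ii - 1] + lt[1, 1]),
                pd1[ii - 1] + lt[2, 1],
            )
            ci[ii] = pred + lbs[ii - 1]
        # delete (consumes T): predecessors on diag k-1 at i
        msk = k - iarr >= 1
        if msk.any():
            ii = iarr[msk]
            pred = np.logaddexp(
                np.logaddexp(pm1[ii] + lt[0, 2], pi1[ii] + lt[1, 2]),
                pd1[ii] + lt[2, 2],
            )
            cd[ii] = pred + lbt[k - ii - 1]

        # begin contributions: predecessor cell is the source (0, 0)
        if k == 1:
            if m >= 1:
                ci[1] = lbeg[1] + lbs[0]
            if n >= 1:
                cd[0] = lbeg[2] + lbt[0]
        elif k == 2 and m >= 1 and n >= 1:
            cm[1] = lbeg[0] + ej[0, 0]

        if keep:
            jarr = k - iarr
            Fm[iarr, jarr] = cm[iarr]
            Fi[iarr, jarr] = ci[iarr]
            Fd[iarr, jarr] = cd[iarr]

        pm2, pi2, pd2 = pm1, pi1, pd1
        pm1, pi1, pd1 = cm, ci, cd

    corner = np.logaddexp(np.logaddexp(pm1[m], pi1[m]), pd1[m])
    total = corner + lstop
    if keep:
        return total, (Fm, Fi, Fd)
    return total, None


def marginal_bits(pair: SequencePair, model: SubstitutionModel,
                  machine: AlignmentMachine, t: float) -> float:
    """I_marginal(<S,T>) at a fixed Markov time, in bits."""
    total, _ = _forward_pass(pair, model, machine, t, keep=False)
    return -total / LOG2


def forward_matrices(pair: SequencePair, model: SubstitutionModel,
                     machine: AlignmentMachine, t: float) -> ForwardMatrices:
    """Full per-state forward matrices (bits) at a fixed Markov time."""
    _, (Fm, Fi, Fd) = _forward_pass(pair, model, machine, t, keep=True)
    return ForwardMatrices(-Fm / LOG2, -Fi / LOG2, -Fd / LOG2, t)


def backward_matrices(pair: SequencePair, model: SubstitutionModel,
                      machine: AlignmentMachine, t: float) -> tuple[np.ndarray, ...]:
    """Per-state backward matrices in natural-log space.

    ``B[x][i, j]`` is the log summed probability of all alignment suffixes
    continuing from state ``x`` at cell (i, j) to termination, including
    the stop factor but excluding the emission at (i, j) itself.
    """
    m, n = pair.shape
    ej, lbs, lbt = _emissions(pair, model, t)
    lt, _, lstop = _machine_logs(machine, t)
    Bm = np.full((m + 1, n + 1), _NEG_INF)
    Bi = np.full((m + 1, n + 1), _NEG_INF)
    Bd = np.full((m + 1, n + 1), _NEG_INF)
    Bm[m, n] = Bi[m, n] = Bd[m, n] = lstop
    for i in range(m, -1, -1):
        for j in range(n, -1, -1):
            if i == m and j == n:
                continue
            cand = []
            if i < m and j < n:
                cand.append((0, ej[i, j] + Bm[i + 1, j + 1]))
            if i < m:
                cand.append((1, lbs[i] + Bi[i + 1, j]))
            if j < n:
                cand.append((2, lbt[j] + Bd[i, j + 1]))
            for x, (Bx,) in enumerate([(Bm,), (Bi,), (Bd,)]):
                acc = _NEG_INF
                for y, v in cand:
                    acc = np.logaddexp(acc, lt[x, y] + v)
                Bx[i, j] = acc
    return Bm, Bi, Bd


# ---------------------------------------------------------------------------
# optimal alignment
# ---------------------------------------------------------------------------

def _viterbi_pass(pair, model, machine, t):
    """Max-product analogue of the forward pass; full matrices in nats."""
    m, n = pair.shape
    ej, lbs, lbt = _emissions(pair, model, t)
    lt, lbeg, lstop = _machine_logs(machine, t)
    Vm = np.full((m + 1, n + 1), _NEG_INF)
    Vi = np.full((m + 1, n + 1), _NEG_INF)
    Vd = np.full((m + 1, n + 1), _NEG_INF)

    neg = np.full(m + 1, _NEG_INF)
    pm2, pi2, pd2 = neg.copy(), neg.copy(), neg.copy()
    pm1, pi1, pd1 = neg.copy(), neg.copy(), neg.copy()
    for k in range(1, m + n + 1):
        lo, hi = max(0, k - n), min(m, k)
        iarr = np.arange(lo, hi + 1)
        cm, ci, cd = neg.copy(), neg.copy(), neg.copy()
        msk = (iarr >= 1) & (k - iarr >= 1)
        if msk.any():
            ii = iarr[msk]
            pred = np.maximum(
                np.maximum(pm2[ii - 1] + lt[0, 0], pi2[ii - 1] + lt[1, 0]),
                pd2[ii - 1] + lt[2, 0],
            )
            cm[ii] = pred + ej[ii - 1, k - ii - 1]
        msk = iarr >= 1
        if msk.any():
            ii = iarr[msk]
            pred = np.maximum(
                np.maximum(pm1[ii - 1] + lt[0, 1], pi1[ii - 1] + lt[1, 1]),
                pd1[ii - 1] + lt[2, 1],
            )
            ci[ii] = pred + lbs[ii - 1]
        msk = k - iarr >= 1
        if msk.any():
            ii = iarr[msk]
            pred = np.maximum(
                np.maximum(pm1[ii] + lt[0, 2], pi1[ii] + lt[1, 2]),
                pd1[ii] + lt[2, 2],
            )
            cd[ii] = pred + lbt[k - ii - 1]
        if k == 1:
            if m >= 1:
                ci[1] = lbeg[1] + lbs[0]
            if n >= 1:
                cd[0] = lbeg[2] + lbt[0]
        elif k == 2 and m >= 1 and n >= 1:
            cm[1] = lbeg[0] + ej[0, 0]
        jarr = k - iarr
        Vm[iarr, jarr] = cm[iarr]
        Vi[iarr, jarr] = ci[iarr]
        Vd[iarr, jarr] = cd[iarr]
        pm2, pi2, pd2 = pm1, pi1, pd1
        pm1, pi1, pd1 = cm, ci, cd
    best = max(Vm[m, n], Vi[m, n], Vd[m, n]) + lstop
    return best, (Vm, Vi, Vd), (ej, lbs, lbt, lt, lbeg)


def optimal_bits(pair, model, machine, t) -> float:
    """Two-part message length of the best alignment at time ``t`` (bits)."""
    best, _, _ = _viterbi_pass(pair, model, machine, t)
    return -best / LOG2


#: traceback preference on ties: match over delete over insert
_TIE_ORDER = (0, 2, 1)


def _traceback(pair, Vs, terms) -> Alignment:
    Vm, Vi, Vd = Vs
    ej, lbs, lbt, lt, lbeg = terms
    m, n = pair.shape
    corner = [Vm[m, n], Vd[m, n], Vi[m, n]]
    state = _TIE_ORDER[int(np.argmax(corner))]
    i, j = m, n
    states = []
    while True:
        states.append("mid"[state])
        if state == 0:
            emis, pi_, pj_ = ej[i - 1, j - 1], i - 1, j - 1
        elif state == 1:
            emis, pi_, pj_ = lbs[i - 1], i - 1, j
        else:
            emis, pi_, pj_ = lbt[j - 1], i, j - 1
        if (pi_, pj_) == (0, 0):
            break
        del emis
        cand = [
            [Vm, Vi, Vd][y][pi_, pj_] + lt[y, state] for y in range(3)
        ]
        # exact ties broken in preference order m > d > i
        best = max(cand)
        for y in _TIE_ORDER:
            if cand[y] == best:
                state = y
                break
        i, j = pi_, pj_
    return Alignment("".join(reversed(states)))


# ---------------------------------------------------------------------------
# Markov-time inference
# ---------------------------------------------------------------------------

def infer_time(objective, bounds: tuple[float, float] = (1.0, 500.0),
               stride: int = 8, xtol: float = 1e-3) -> float:
    """Minimize a one-dimensional objective over Markov time.

    A coarse integer-grid scan locates the basin; bounded golden-section
    search refines it.  Deterministic; on a flat objective the lower bound
    is returned (documented tie-break).
    """
    t_min, t_max = bounds
    grid = list(np.arange(t_min, t_max, stride, dtype=float)) + [float(t_max)]
    vals = np.array([objective(t) for t in grid])
    if logger.isEnabledFor(logging.DEBUG):
        for t, v in zip(grid, vals):
            logger.debug("time objective: t=%.3f value=%.6f", t, v)
    if not np.isfinite(vals).any():
        raise InferenceError("objective is non-finite over the whole time grid")
    if np.nanmax(vals) - np.nanmin(vals) < 1e-12:
        return float(t_min)
    k = int(np.nanargmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi - lo < xtol:
        return float(grid[k])
    # golden-section search on [lo, hi]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = objective(c), objective(d)
    while b - a > xtol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = objective(d)
    t_best = (a + b) / 2.0
    # never worse than the best grid point
    if objective(t_best) <= vals[k] + 1e-12:
        return float(t_best)
    return float(grid[k])


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

def alignment_length(pair: SequencePair, alignment: Alignment,
                     model: SubstitutionModel, machine: AlignmentMachine,
                     t: float) -> float:
    """Two-part message length I(A, <S,T>) of a given alignment (bits),
    recomputed directly from its three-state string."""
    m, n = pair.shape
    alignment.require_pair(m, n)
    ej, lbs, lbt = _emissions(pair, model, t)
    lt, lbeg, lstop = _machine_logs(machine, t)
    code = {"m": 0, "i": 1, "d": 2}
    nats = lstop
    prev = None
    i = j = 0
    for c in alignment.states:
        x = code[c]
        nats += lbeg[x] if prev is None else lt[prev, x]
        if c == "m":
            nats += ej[i, j]; i += 1; j += 1
        elif c == "i":
            nats += lbs[i]; i += 1
        else:
            nats += lbt[j]; j += 1
        prev = x
    return -nats / LOG2


def optimal_compare(pair: SequencePair, model: SubstitutionModel,
                    machine: AlignmentMachine, t: float | None = None,
                    bounds=(1.0, 500.0), stride: int = 8) -> ComparisonResult:
    """Best single alignment, jointly minimized over Markov time."""
    if t is None:
        t = infer_time(lambda u: optimal_bits(pair, model, machine, u),
                       bounds=bounds, stride=stride)
    best, Vs, terms = _viterbi_pass(pair, model, machine, t)
    aln = _traceback(pair, Vs, terms)
    return ComparisonResult(
        null_bits=null_length(pair, model),
        i_optimal_bits=-best / LOG2,
        time_optimal=float(t),
        optimal_alignment=aln,
    )


def marginal_compare(pair: SequencePair, model: SubstitutionModel,
                     machine: AlignmentMachine, t: float | None = None,
                     bounds=(1.0, 500.0), stride: int = 8
                     ) -> tuple[ComparisonResult, ForwardMatrices]:
    """Marginal probability of relatedness, minimized over Markov time."""
    if t is None:
        t = infer_time(lambda u: marginal_bits(pair, model, machine, u),
                       bounds=bounds, stride=stride)
    fwd = forward_matrices(pair, model, machine, t)
    i_marg = fwd.total_bits() - math.log2(machine.stop)
    result = ComparisonResult(
        null_bits=null_length(pair, model),
        i_marginal_bits=i_marg,
        time_marginal=float(t),
    )
    return result, fwd


def compare_pair(pair: SequencePair, model: SubstitutionModel,
                 machine: AlignmentMachine, bounds=(1.0, 500.0),
                 stride: int = 8) -> tuple[ComparisonResult, ForwardMatrices]:
    """Full comparison: optimal and marginal statistics with their own
    inferred times, sharing one null-model length."""
    opt = optimal_compare(pair, model, machine, bounds=bounds, stride=stride)
    marg, fwd = marginal_compare(pair, model, machine, bounds=bounds, stride=stride)
    opt.i_marginal_bits = marg.i_marginal_bits
    opt.time_marginal = marg.time_marginal
    return opt, fwd


def significance(result: ComparisonResult) -> dict:
    """MML null test: a model is accepted iff it compresses better than the
    null (delta > 0); delta of exactly zero is rejected."""
    out = {}
    if result.delta_optimal_bits is not None:
        out["optimal_significant"] = result.delta_optimal_bits > 0
    if result.delta_marginal_bits is not None:
        out["marginal_significant"] = result.delta_marginal_bits > 0
    return out


# ---------------------------------------------------------------------------
# marginal landscape
# ---------------------------------------------------------------------------

def _prefix_bits(pair, model, machine, t) -> np.ndarray:
    """-log2 marginal probability of every prefix pair <S[1..i], T[1..j]>,
    with the empty prefix assigned probability 1."""
    _, (Fm, Fi, Fd) = _forward_pass(pair, model, machine, t, keep=True)
    stack = np.stack([Fm, Fi, Fd])
    with np.errstate(invalid="ignore"):
        mx = stack.max(axis=0)
        tot = mx + np.log(np.exp(stack - mx).sum(axis=0))
    tot[np.isneginf(mx)] = _NEG_INF
    bits = -(tot + math.log(machine.stop)) / LOG2
    bits[0, 0] = 0.0
    return bits


def landscape(pair: SequencePair, model: SubstitutionModel,
              machine: AlignmentMachine, t: float) -> Landscape:
    """Marginal probability landscape at time ``t``.

    Cell (i, j) holds the negative base-2 log of the product of the
    marginal probability that the prefixes <S[1..i], T[1..j]> are related
    and the marginal probability that the suffixes <S[i+1..], T[j+1..]>
    are related (the latter evaluated on the reversed pair; by machine
    reversibility this equals the forward suffix marginal).
    """
    pre = _prefix_bits(pair, model, machine, t)
    rev = _prefix_bits(pair.reversed(), model, machine, t)
    suf = rev[::-1, ::-1]
    i_marg = pre[-1, -1]
    return Landscape(pre + suf, t, i_marg)
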