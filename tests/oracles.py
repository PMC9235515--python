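"""Independent brute-force oracles used to validate the dynamic programs.

Everything here works by exhaustive enumeration or explicit path walking
with scalar arithmetic; none of it shares code with the package's
anti-diagonal DPs or rescaling machinery.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from alnzone.models import AA_ORDER

STATE_CODE = {"m": 0, "i": 1, "d": 2}
AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}


@lru_cache(maxsize=None)
def enumerate_alignments(m: int, n: int) -> tuple[str, ...]:
    """All three-state strings aligning sequences of lengths m and n."""
    out: list[str] = []

    def rec(i: int, j: int, acc: list[str]) -> None:
        if i == m and j == n:
            out.append("".join(acc))
            return
        if i < m and j < n:
            acc.append("m"); rec(i + 1, j + 1, acc); acc.pop()
        if i < m:
            acc.append("i"); rec(i + 1, j, acc); acc.pop()
        if j < n:
            acc.append("d"); rec(i, j + 1, acc); acc.pop()

    rec(0, 0, [])
    return tuple(out)


def joint_probability(s: str, t: str, states: str, model, machine, time: float) -> float:
    """Scalar joint probability Pr(A, <S,T>) of one alignment path."""
    T = machine.transition(time)
    begin = machine.begin(time)
    Mt = model.matrix_at_time(time)
    pi = model.stationary
    p = 1.0
    prev = None
    i = j = 0
    for c in states:
        x = STATE_CODE[c]
        p *= begin[x] if prev is None else T[prev, x]
        if c == "m":
            a, b = AA_INDEX[s[i]], AA_INDEX[t[j]]
            p *= pi[a] * Mt[a, b]
            i += 1
            j += 1
        elif c == "i":
            p *= pi[AA_INDEX[s[i]]]
            i += 1
        else:
            p *= pi[AA_INDEX[t[j]]]
            j += 1
        prev = x
    return p * machine.stop


def all_joint_probabilities(pair, model, machine, time: float) -> tuple[tuple[str, ...], np.ndarray]:
    alns = enumerate_alignments(*pair.shape)
    probs = np.array([joint_probability(pair.s, pair.t, a, model, machine, time)
                      for a in alns])
    return alns, probs


def walk_profile(states: str) -> np.ndarray:
    """Skew-diagonal crossing profile from the explicit vertex list.

    The path's lattice vertices are listed; the crossing of skew diagonal
    k is read off a vertex with i+j == k, or — when a diagonal move jumps
    from k-1 to k+1 — from the (constant) proper diagonal of that move.
    """
    verts = [(0, 0)]
    i = j = 0
    for c in states:
        if c == "m":
            i, j = i + 1, j + 1
        elif c == "i":
            i += 1
        else:
            j += 1
        verts.append((i, j))
    total = i + j
    pi = np.zeros(total + 1, dtype=np.int64)
    for k in range(total + 1):
        hit = [v for v in verts if v[0] + v[1] == k]
        if hit:
            pi[k] = hit[0][1] - hit[0][0]
        else:
            # mid-move crossing: find the diagonal edge spanning k
            for (i0, j0), (i1, j1) in zip(verts, verts[1:]):
                if i0 + j0 == k - 1 and i1 + j1 == k + 1:
                    pi[k] = j0 - i0
                    break
            else:  # pragma: no cover
                raise AssertionError(f"no crossing found at skew {k}")
    return pi


def walk_distance(states1: str, states2: str) -> int:
    p1, p2 = walk_profile(states1), walk_profile(states2)
    return int(np.abs(p1 - p2).sum())


def brute_expected_distance(pair, ref_states: str, model, machine, time: float) -> float:
    """Posterior-weighted expected distance by full enumeration (raw)."""
    alns, probs = all_joint_probabilities(pair, model, machine, time)
    post = probs / probs.sum()
    dists = np.array([walk_distance(a, ref_states) for a in alns])
    return float((post * dists).sum())
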