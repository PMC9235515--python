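"""Alignment paths and the skew-diagonal inter-alignment distance.

An alignment of sequences S and T is a three-state string over
``{m, i, d}`` — equivalently a monotone source-to-sink lattice path from
(0, 0) to (|S|, |T|), where ``m`` steps diagonally (consuming one residue
of each sequence), ``i`` steps vertically (consuming S) and ``d`` steps
horizontally (consuming T).

Every such path crosses each skew diagonal ``k = i + j`` of the lattice
exactly once.  Recording the signed proper diagonal ``j - i`` at each
crossing gives the alignment's diagonal profile; the distance between two
alignments is the L1 distance between their profiles — the summed width
between the two paths across all skew diagonals.  This grades near-misses
smoothly instead of scoring columns as identical/not-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, FormatError

__all__ = [
    "Alignment",
    "DiagonalProfile",
    "diagonal_profile",
    "alignment_distance",
    "normalized_distance",
]

_STATES = frozenset("mid")


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment as a three-state string.

    ``m`` consumes one residue of each sequence, ``i`` one residue of S
    (vertical step), ``d`` one residue of T (horizontal step).
    """

    states: str

    def __post_init__(self):
        if not self.states or not set(self.states) <= _STATES:
            raise FormatError(
                f"alignment state string must be non-empty over 'mid', got {self.states!r}"
            )

    @property
    def s_length(self) -> int:
        return sum(1 for c in self.states if c in "mi")

    @property
    def t_length(self) -> int:
        return sum(1 for c in self.states if c in "md")

    def __len__(self) -> int:
        return len(self.states)

    def matches_pair(self, m: int, n: int) -> bool:
        return self.s_length == m and self.t_length == n

    def require_pair(self, m: int, n: int) -> None:
        if not self.matches_pair(m, n):
            raise ConsistencyError(
                f"alignment consumes ({self.s_length}, {self.t_length}) residues "
                f"but the pair has lengths ({m}, {n})"
            )

    # -- gapped representation ------------------------------------------

    def gapped(self, s: str, t: str) -> tuple[str, str]:
        """Render as two equal-length gapped strings with ``-`` gaps."""
        self.require_pair(len(s), len(t))
        row_s, row_t = [], []
        i = j = 0
        for c in self.states:
            if c == "m":
                row_s.append(s[i]); row_t.append(t[j]); i += 1; j += 1
            elif c == "i":
                row_s.append(s[i]); row_t.append("-"); i += 1
            else:
                row_s.append("-"); row_t.append(t[j]); j += 1
        return "".join(row_s), "".join(row_t)

    @classmethod
    def from_gapped(cls, gapped_s: str, gapped_t: str, strict: bool = True) -> "Alignment":
        """Build from two equal-length gapped strings.

        A column gapped in both rows is meaningless for a pairwise path:
        rejected in strict mode, dropped with the state string shortened
        otherwise.
        """
        if len(gapped_s) != len(gapped_t):
            raise FormatError(
                f"gapped rows differ in length ({len(gapped_s)} vs {len(gapped_t)})"
            )
        states = []
        for col, (a, b) in enumerate(zip(gapped_s, gapped_t)):
            if a == "-" and b == "-":
                if strict:
                    raise FormatError(f"column {col} is gapped in both sequences")
                continue
            states.append("m" if (a != "-" and b != "-") else ("i" if b == "-" else "d"))
        return cls("".join(states))


@dataclass(frozen=True)
class DiagonalProfile:
    """Proper-diagonal crossing indices of a path, per skew diagonal.

    ``pi[k]`` is the signed proper diagonal ``j - i`` at which the path
    crosses skew diagonal ``k``, for ``k`` in ``0..|S|+|T|``.
    """

    pi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=np.int64))


def diagonal_profile(alignment: Alignment) -> DiagonalProfile:
    """Walk the path from (0, 0) recording each skew-diagonal crossing.

    A match step from (i, j) to (i+1, j+1) crosses skew diagonals
    ``i+j+1`` (mid-move) and ``i+j+2``, both at the move's constant proper
    diagonal ``j - i``; an insert/delete step crosses only ``i+j+1``.
    """
    m, n = alignment.s_length, alignment.t_length
    pi = np.zeros(m + n + 1, dtype=np.int64)
    i = j = 0
    for c in alignment.states:
        if c == "m":
            pi[i + j + 1] = j - i
            pi[i + j + 2] = j - i
            i += 1
            j += 1
        elif c == "i":
            pi[i + j + 1] = j - i - 1
            i += 1
        else:
            pi[i + j + 1] = j - i + 1
            j += 1
    return DiagonalProfile(pi)


def alignment_distance(a1: Alignment, a2: Alignment) -> int:
    """Summed width between the two paths over all skew diagonals:
    ``sum_k |pi1[k] - pi2[k]|``.  Zero iff the state strings are equal."""
    if (a1.s_length, a1.t_length) != (a2.s_length, a2.t_length):
        raise ConsistencyError(
            f"alignments are for different pair lengths: "
            f"({a1.s_length},{a1.t_length}) vs ({a2.s_length},{a2.t_length})"
        )
    p1 = diagonal_profile(a1).pi
    p2 = diagonal_profile(a2).pi
    return int(np.abs(p1 - p2).sum())


def normalized_distance(d: float, m: int, n: int) -> float:
    """Distance divided by ``m + n``, the maximum possible alignment length,
    so values are comparable across pairs of different sizes."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be at least 1")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return d / (m + n)
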