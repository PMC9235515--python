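"""Amino-acid alphabet, time-parameterized substitution models and the
three-state alignment machine.

A substitution model is a base stochastic matrix ``M`` of amino-acid
interchange for one unit of Markov time together with its stationary
distribution ``pi``.  Divergence is parameterized by a continuous Markov
time ``t``; the conditional interchange matrix at time ``t`` is the matrix
power ``M**t`` (computed by eigendecomposition so that fractional times are
well defined), and the joint probability of observing amino acids ``(a, b)``
in a matched alignment column is ``pi[a] * (M**t)[a, b]``.

The alignment machine is a three-state automaton over {match, insert,
delete} whose transition probabilities vary smoothly with the same Markov
time: as sequences diverge, match runs shorten and gaps become more
frequent.  The machine is reversible (detailed balance with respect to its
stationary state-occupancy), and alignments are scored starting from that
stationary distribution, which makes the marginal probability of a sequence
pair exactly invariant under reversing both sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import AlphabetError, ModelError

__all__ = [
    "Alphabet",
    "ALPHABET",
    "X_INDEX",
    "SubstitutionModel",
    "MachineParameters",
    "AlignmentMachine",
    "bundled_model_names",
    "load_model",
    "matrix_at_time",
    "expected_change",
    "joint_match_probability",
]

#: canonical one-letter order used throughout (PAM-style ordering)
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: internal index used for the averaged "unknown residue" pseudo-symbol
X_INDEX = 20

# one-to-one ambiguity resolutions applied in the lenient policy
_LENIENT_MAP = {"B": "D", "Z": "E", "U": "C"}


class Alphabet:
    """The 20 standard amino acids with an index bijection.

    ``resolve`` applies the residue policy: in ``strict`` mode only the 20
    canonical symbols are accepted; in ``lenient`` mode B/Z/U are mapped to
    D/E/C and X is mapped to the averaged pseudo-residue (index 20), whose
    encoding cost is the stationary-weighted mean cost of the 20 residues.
    """

    def __init__(self, symbols: str = AA_ORDER):
        if len(symbols) != 20 or len(set(symbols)) != 20:
            raise ModelError("alphabet must contain exactly 20 unique symbols")
        self.symbols = symbols
        self.index = {s: i for i, s in enumerate(symbols)}

    def __len__(self) -> int:
        return 20

    def resolve(self, symbol: str, policy: str = "lenient") -> int:
        """Map a one-letter code to an internal index (0..19, or 20 for X)."""
        s = symbol.upper()
        if s in self.index:
            return self.index[s]
        if policy == "strict":
            raise AlphabetError(f"unknown residue {symbol!r} (strict policy)")
        if s in _LENIENT_MAP:
            return self.index[_LENIENT_MAP[s]]
        if s == "X":
            return X_INDEX
        raise AlphabetError(f"unresolvable residue {symbol!r}")

    def encode(self, sequence: str, policy: str = "lenient") -> np.ndarray:
        return np.array([self.resolve(c, policy) for c in sequence], dtype=np.intp)


ALPHABET = Alphabet()


@dataclass
class SubstitutionModel:
    """A time-parameterized stochastic model of amino-acid interchange.

    Parameters
    ----------
    name
        Human-readable label, e.g. ``"mmlsum-like"``.
    base_matrix
        20x20 row-stochastic conditional matrix for one unit of Markov time.
    stationary
        Length-20 probability vector; a left fixed point of ``base_matrix``.
    """

    name: str
    base_matrix: np.ndarray
    stationary: np.ndarray
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.base_matrix, dtype=float)
        pi = np.asarray(self.stationary, dtype=float)
        if M.shape != (20, 20):
            raise ModelError(f"base matrix must be 20x20, got {M.shape}")
        if pi.shape != (20,):
            raise ModelError(f"stationary must have length 20, got {pi.shape}")
        if (M < 0).any() or (pi < 0).any():
            raise ModelError("negative probabilities in substitution model")
        if not np.allclose(M.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ModelError("base matrix rows must sum to 1 (within 1e-12)")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ModelError("stationary must sum to 1 (within 1e-12)")
        if np.abs(pi @ M - pi).max() > 1e-8:
            raise ModelError("stationary is not a left fixed point of the base matrix")
        self.base_matrix = M
        self.stationary = pi

    # -- matrix powers ---------------------------------------------------

    def _eigendecomposition(self):
        if self._eig is None:
            w, V = np.linalg.eig(self.base_matrix)
            self._eig = (w, V, np.linalg.inv(V))
        return self._eig

    def matrix_at_time(self, t: float) -> np.ndarray:
        """Conditional interchange matrix ``M**t`` for Markov time ``t >= 0``.

        Fractional powers use the eigendecomposition of the base matrix;
        tiny negative entries from round-off (> -1e-12) are clamped to zero
        and rows renormalized, preserving stochasticity.
        """
        if t < 0:
            raise ValueError(f"Markov time must be non-negative, got {t}")
        w, V, Vinv = self._eigendecomposition()
        with np.errstate(invalid="ignore"):
            wt = np.power(w.astype(complex), t)
        Mt = (V * wt) @ Vinv
        Mt = np.real(Mt)
        if Mt.min() < -1e-9:
            raise ModelError(
                f"matrix power at t={t} produced entry {Mt.min():.3g}; "
                "base matrix is not embeddable at this time"
            )
        Mt = np.clip(Mt, 0.0, None)
        Mt /= Mt.sum(axis=1, keepdims=True)
        return Mt

    def expected_change(self, t: float) -> float:
        """Expected %-change of amino acids after Markov time ``t``.

        ``100 * (1 - sum_a pi[a] * (M**t)[a, a])`` — the stationary-weighted
        probability that a site holds a different residue after time ``t``.
        Non-decreasing in ``t`` for reversible models.
        """
        Mt = self.matrix_at_time(t)
        return 100.0 * (1.0 - float(self.stationary @ np.diag(Mt)))

    def joint_match_probability(self, t: float, a: str, b: str) -> float:
        """Joint probability ``pi[a] * (M**t)[a, b]`` of a matched column."""
        ia = ALPHABET.resolve(a, policy="strict")
        ib = ALPHABET.resolve(b, policy="strict")
        return float(self.stationary[ia] * self.matrix_at_time(t)[ia, ib])

    # -- log-probability tables used by the dynamic programs -------------

    def log_background(self) -> np.ndarray:
        """Natural-log 20-nomial probabilities, extended with the averaged
        X pseudo-residue at index 20 (stationary-weighted mean log-prob)."""
        lp = np.log(self.stationary)
        out = np.empty(21)
        out[:20] = lp
        out[X_INDEX] = float(self.stationary @ lp)
        return out

    def log_joint(self, t: float) -> np.ndarray:
        """Natural-log joint match probabilities at time ``t`` as a 21x21
        table; row/column 20 hold the averaged X pseudo-residue."""
        with np.errstate(divide="ignore"):
            lj = np.log(self.stationary[:, None] * self.matrix_at_time(t))
        pi = self.stationary
        out = np.full((21, 21), -np.inf)
        out[:20, :20] = lj
        out[X_INDEX, :20] = pi @ lj
        out[:20, X_INDEX] = lj @ pi
        out[X_INDEX, X_INDEX] = pi @ lj @ pi
        return out

    # -- file I/O --------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "SubstitutionModel":
        """Read the plain-text dialect: comment lines start with ``#``; the
        first data line is the 20-symbol order, then 20 rows of 20
        conditional probabilities, then one stationary row."""
        path = Path(path)
        lines = [
            ln.strip()
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        if len(lines) != 22:
            raise ModelError(
                f"{path}: expected 22 data lines (symbols, 20 rows, stationary), "
                f"got {len(lines)}"
            )
        symbols = "".join(lines[0].split())
        rows = np.array([[float(x) for x in ln.split()] for ln in lines[1:21]])
        pi = np.array([float(x) for x in lines[21].split()])
        if symbols != AA_ORDER:
            # reorder into canonical order
            order = [symbols.index(s) for s in AA_ORDER]
            rows = rows[np.ix_(order, order)]
            pi = pi[order]
        return cls(name or path.stem, rows, pi)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# substitution model: {self.name}\n")
            fh.write(" ".join(AA_ORDER) + "\n")
            for row in self.base_matrix:
                fh.write(" ".join(f"{x:.17e}" for x in row) + "\n")
            fh.write(" ".join(f"{x:.17e}" for x in self.stationary) + "\n")


# -- bundled models -------------------------------------------------------

_BUNDLED = {
    "pam-like": "pam_like_synthetic.model",
    "blosum-like": "blosum_like_synthetic.model",
    "vtml-like": "vtml_like_synthetic.model",
    "mmlsum-like": "mmlsum_like_synthetic.model",
}


def bundled_model_names() -> list[str]:
    return sorted(_BUNDLED)


def load_model(name_or_path: str | Path) -> SubstitutionModel:
    """Load a bundled model by name (``mmlsum-like`` etc.) or any model file
    by path."""
    key = str(name_or_path).lower()
    if key in _BUNDLED:
        ref = resources.files("alnzone.data") / _BUNDLED[key]
        with resources.as_file(ref) as p:
            return SubstitutionModel.from_file(p, name=key)
    p = Path(name_or_path)
    if not p.exists():
        raise ModelError(
            f"unknown model {name_or_path!r}; bundled: {', '.join(bundled_model_names())}"
        )
    return SubstitutionModel.from_file(p)


# -- module-level convenience wrappers ------------------------------------

def matrix_at_time(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.matrix_at_time(t)


def expected_change(model: SubstitutionModel, t: float) -> float:
    return model.expected_change(t)


def joint_match_probability(model: SubstitutionModel, t: float, a: str, b: str) -> float:
    return model.joint_match_probability(t, a, b)


# -- the three-state alignment machine ------------------------------------

@dataclass(frozen=True)
class MachineParameters:
    """Tunable parameters of the default alignment machine.

    ``stop`` is the per-step termination mass (mean alignment length
    ``1/stop``).  Match-state occupancy decays from
    ``occupancy_floor + occupancy_range`` toward ``occupancy_floor`` with
    timescale ``occupancy_timescale``; the gap-open probability rises from
    ``gap_open_floor`` toward ``gap_open_floor + gap_open_range`` with
    timescale ``gap_open_timescale``; ``cross_gap`` is the direct
    insert<->delete switch probability.
    """

    stop: float = 0.002
    occupancy_floor: float = 0.55
    occupancy_range: float = 0.40
    occupancy_timescale: float = 300.0
    gap_open_floor: float = 0.01
    gap_open_range: float = 0.04
    gap_open_timescale: float = 200.0
    cross_gap: float = 0.05


class AlignmentMachine:
    """Time-parameterized three-state (match/insert/delete) machine.

    State order everywhere is ``(m, i, d) = (0, 1, 2)``.  At every time the
    machine satisfies detailed balance with respect to its stationary
    occupancy ``(mu, (1-mu)/2, (1-mu)/2)``, and that occupancy is also the
    begin-state distribution, so alignment probabilities are invariant under
    reversing both sequences.  The per-step stop mass is constant; each
    row of the transition matrix sums to ``1 - stop``.
    """

    M, I, D = 0, 1, 2

    def __init__(self, params: MachineParameters | None = None):
        self.params = params or MachineParameters()
        p = self.params
        if not (0 < p.stop < 0.5):
            raise ModelError("stop probability must be in (0, 0.5)")
        # validate across the usual time range
        for t in (0.0, 1.0, 500.0, 1e4):
            self.transition(t)

    def match_occupancy(self, t: float) -> float:
        p = self.params
        return p.occupancy_floor + p.occupancy_range * math.exp(-t / p.occupancy_timescale)

    def gap_open(self, t: float) -> float:
        p = self.params
        return p.gap_open_floor + p.gap_open_range * (
            1.0 - math.exp(-t / p.gap_open_timescale)
        )

    def begin(self, t: float) -> np.ndarray:
        """Begin-state distribution = stationary occupancy at time ``t``."""
        mu = self.match_occupancy(t)
        return np.array([mu, (1.0 - mu) / 2.0, (1.0 - mu) / 2.0])

    def transition(self, t: float) -> np.ndarray:
        """3x3 transition matrix at time ``t`` (rows sum to ``1 - stop``)."""
        if t < 0:
            raise ValueError(f"Markov time must be non-negative, got {t}")
        p = self.params
        rho = p.stop
        mu = self.match_occupancy(t)
        g = self.gap_open(t)
        close = 2.0 * g * mu / (1.0 - mu)  # detailed balance: mu*g = pi_gap*close
        c = p.cross_gap
        extend = 1.0 - rho - close - c
        if extend < 0 or (1.0 - rho - 2.0 * g) < 0:
            raise ModelError(
                f"machine parameters invalid at t={t}: gap-close {close:.3f} "
                f"too large (reduce gap_open or raise cross_gap headroom)"
            )
        T = np.array(
            [
                [1.0 - rho - 2.0 * g, g, g],
                [close, extend, c],
                [close, c, extend],
            ]
        )
        return T

    @property
    def stop(self) -> float:
        return self.params.stop

    def with_params(self, **kw) -> "AlignmentMachine":
        return AlignmentMachine(replace(self.params, **kw))
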