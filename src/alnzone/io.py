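"""FASTA, reference-alignment and results I/O."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO

from .align_distance import Alignment
from .errors import ConsistencyError, FormatError
from .mml_core import ComparisonResult, Landscape, SequencePair

__all__ = ["read_pair", "read_reference_alignment", "write_results",
           "write_landscape", "RESULT_COLUMNS"]


def _records(path: str | Path):
    try:
        return list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse FASTA ({exc})") from exc


def read_pair(path: str | Path, second: str | Path | None = None,
              policy: str = "lenient") -> SequencePair:
    """Read a sequence pair from one two-record FASTA file, or two
    single-record files."""
    if second is not None:
        ra, rb = _records(path), _records(second)
        if len(ra) != 1 or len(rb) != 1:
            raise FormatError(
                f"expected one record per file, got {len(ra)} in {path} "
                f"and {len(rb)} in {second}"
            )
        recs = [ra[0], rb[0]]
    else:
        recs = _records(path)
        if len(recs) != 2:
            raise FormatError(f"{path}: expected exactly 2 records, got {len(recs)}")
    s, t = (str(r.seq).upper().replace("-", "") for r in recs)
    if not s or not t:
        raise FormatError(f"{path}: empty sequence record")
    return SequencePair(s, t, s_id=recs[0].id, t_id=recs[1].id, policy=policy)


def read_reference_alignment(path: str | Path, pair: SequencePair,
                             strict: bool = True) -> Alignment:
    """Read a gapped pairwise FASTA whose ungapped sequences must match the
    pair exactly; returns the three-state alignment."""
    recs = _records(path)
    if len(recs) != 2:
        raise FormatError(f"{path}: expected exactly 2 records, got {len(recs)}")
    gs, gt = (str(r.seq).upper() for r in recs)
    aln = Alignment.from_gapped(gs, gt, strict=strict)
    for label, gapped, expect in (("S", gs, pair.s), ("T", gt, pair.t)):
        ungapped = gapped.replace("-", "")
        if ungapped != expect.upper():
            pos = next(
                (k for k, (a, b) in enumerate(zip(ungapped, expect.upper())) if a != b),
                min(len(ungapped), len(expect)),
            )
            raise ConsistencyError(
                f"{path}: reference {label} disagrees with the pair at "
                f"ungapped position {pos}"
            )
    return aln


RESULT_COLUMNS = [
    "pair_id", "s_len", "t_len", "null_bits", "i_optimal_bits",
    "i_marginal_bits", "delta_optimal", "delta_marginal",
    "time_optimal", "time_marginal",
]


def _fmt(value, decimals: int) -> str:
    if value is None:
        return "NA"
    return f"{value:.{decimals}f}"


def write_results(records: list[tuple[str, tuple[int, int], ComparisonResult]],
                  path: str | Path, extra: dict | None = None,
                  provenance: dict | None = None) -> None:
    """Write comparison results as TSV (bits to 1 decimal, times to 1).

    ``records`` holds (pair id, (|S|, |T|), result) triples; ``extra`` maps
    column name to a per-record list of additional values (e.g. expected
    distances, written to 3 decimals).  ``provenance`` entries (model,
    machine parameters, seeds, version) are embedded as ``#`` comment
    lines so the computation can be re-run exactly.
    """
    extra = extra or {}
    path = Path(path)
    cols = RESULT_COLUMNS + sorted(extra)
    with path.open("w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("\t".join(cols) + "\n")
        for idx, (pid, (m, n), res) in enumerate(records):
            row = [
                pid, str(m), str(n),
                _fmt(res.null_bits, 1), _fmt(res.i_optimal_bits, 1),
                _fmt(res.i_marginal_bits, 1),
                _fmt(res.delta_optimal_bits, 1), _fmt(res.delta_marginal_bits, 1),
                _fmt(res.time_optimal, 1), _fmt(res.time_marginal, 1),
            ]
            for name in sorted(extra):
                row.append(_fmt(extra[name][idx], 3))
            fh.write("\t".join(row) + "\n")


def write_landscape(ls: Landscape, path: str | Path) -> None:
    """Dense text export of a marginal landscape matrix."""
    header = (f"# marginal landscape; t={ls.t:.3f}; "
              f"i_marginal_bits={ls.i_marginal_bits:.6f}")
    np.savetxt(path, ls.matrix, fmt="%.6f", header=header)
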