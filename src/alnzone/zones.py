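"""Divergence-zone classification and survey summaries.

Inferred Markov time partitions sequence relationships into zones:
daylight (t <= 150, sequence alignments closely agree with structure
alignments), twilight (150 < t <= 250, residue-level correspondences
become unreliable), midnight (250 < t <= 350, drastic quartile variance —
sequence alignments should be ignored) and beyond (t > 350, diverged past
the limit of inference).  Boundary times are inclusive on the lower zone.

Surveys of many pairs are summarized as per-integer-time-bin quartiles of
the normalized expected distance plus the cumulative pair-count growth —
the desk-scale analogue of the large-survey quartile-versus-time plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ZoneThresholds", "classify_zone", "compression_group",
           "quartile_summary"]


@dataclass(frozen=True)
class ZoneThresholds:
    """Zone boundaries in Markov time units (must be strictly increasing)."""

    daylight_max: float = 150.0
    twilight_max: float = 250.0
    midnight_max: float = 350.0

    def __post_init__(self):
        if not (0 < self.daylight_max < self.twilight_max < self.midnight_max):
            raise ValueError("zone thresholds must be strictly increasing")


DEFAULT_THRESHOLDS = ZoneThresholds()

ZONES = ("daylight", "twilight", "midnight", "beyond")


def classify_zone(time: float, thresholds: ZoneThresholds = DEFAULT_THRESHOLDS) -> str:
    """Zone label for an inferred Markov time (boundaries inclusive below)."""
    if time < 0:
        raise ValueError(f"Markov time must be non-negative, got {time}")
    if time <= thresholds.daylight_max:
        return "daylight"
    if time <= thresholds.twilight_max:
        return "twilight"
    if time <= thresholds.midnight_max:
        return "midnight"
    return "beyond"


def compression_group(delta_optimal: float, delta_marginal: float) -> str:
    """Compression-based significance group of a pair.

    group1: the optimal alignment beats the null (delta_optimal > 0);
    group2: only the marginal beats the null; group3: neither does.
    """
    if not (np.isfinite(delta_optimal) and np.isfinite(delta_marginal)):
        raise ValueError("compression deltas must be finite")
    if delta_optimal > 0:
        return "group1"
    if delta_marginal > 0:
        return "group2"
    return "group3"


def quartile_summary(records: pd.DataFrame,
                     time_range: tuple[int, int] = (1, 500)) -> pd.DataFrame:
    """Per-integer-time-bin quartiles of normalized expected distance.

    ``records`` needs columns ``time_marginal`` and ``expected_distance``.
    Returns one row per populated bin with Q1/Q2/Q3 (linear-interpolation
    quartiles), the pair count, and the cumulative percentage of pairs at
    or below each bin.
    """
    if len(records) == 0:
        raise ValueError("survey is empty")
    lo, hi = time_range
    t = np.clip(np.round(records["time_marginal"].to_numpy()), lo, hi).astype(int)
    d = records["expected_distance"].to_numpy(dtype=float)
    rows = []
    for b in np.unique(t):
        sel = d[t == b]
        q1, q2, q3 = np.percentile(sel, [25, 50, 75])
        rows.append({"bin": int(b), "q1": q1, "q2": q2, "q3": q3,
                     "count": int(sel.size)})
    out = pd.DataFrame(rows).sort_values("bin", ignore_index=True)
    out["cumulative_pct"] = 100.0 * out["count"].cumsum() / out["count"].sum()
    return out
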