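"""GC/AT composition statistics for recovered coding sequences.

High GC content is a leading explanation for genes dropping out of
avian genome assemblies and annotations, so the pipeline characterises
every recovered sequence: GC percentage, AT-richness (AT% > 60, strict),
GC-content bins, and GC-stretch profiles (maximal runs of consecutive
G/C bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CompositionRecord",
    "gc_content",
    "classify_at_rich",
    "gc_bins",
    "gc_stretch_profile",
    "composition_table",
]


def gc_content(sequence: str) -> float:
    """GC percentage: 100·(G+C)/(A+C+G+T).

    Ambiguous characters are excluded from numerator and denominator;
    an empty effective denominator raises.
    """
    s = str(sequence).upper().replace("U", "T")
    gc = sum(s.count(b) for b in "GC")
    at = sum(s.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return 100.0 * gc / (gc + at)


def classify_at_rich(at_percent: float, threshold: float = 60.0) -> bool:
    """AT-rich iff AT% strictly exceeds the threshold (default 60)."""
    return at_percent > threshold


def gc_stretch_profile(
    sequence: str, min_lengths: Sequence[int] = (5, 10, 20)
) -> tuple[int, dict[int, int]]:
    """Longest maximal G/C run and counts of maximal runs >= each cutoff."""
    s = str(sequence).upper()
    runs: list[int] = []
    cur = 0
    for ch in s:
        if ch in "GC":
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    longest = max(runs, default=0)
    counts = {m: sum(1 for r in runs if r >= m) for m in min_lengths}
    return longest, counts


@dataclass(frozen=True)
class CompositionRecord:
    """Per-sequence composition summary."""

    id: str
    length: int
    gc_percent: float
    at_percent: float
    at_rich: bool
    longest_gc_stretch: int
    gc_stretch_counts: Mapping[int, int] = field(default_factory=dict)


def composition_record(
    seq_id: str,
    sequence: str,
    at_rich_threshold: float = 60.0,
    stretch_min_lengths: Sequence[int] = (5, 10, 20),
) -> CompositionRecord:
    gc = gc_content(sequence)
    at = 100.0 - gc
    longest, counts = gc_stretch_profile(sequence, stretch_min_lengths)
    return CompositionRecord(
        id=seq_id, length=len(sequence), gc_percent=gc, at_percent=at,
        at_rich=classify_at_rich(at, at_rich_threshold),
        longest_gc_stretch=longest, gc_stretch_counts=counts,
    )


def composition_table(
    records: Iterable, at_rich_threshold: float = 60.0,
    stretch_min_lengths: Sequence[int] = (5, 10, 20),
) -> pd.DataFrame:
    """One CompositionRecord row per (id, seq)-like input record."""
    rows = []
    for rec in records:
        seq_id = getattr(rec, "id", None) or rec[0]
        seq = str(getattr(rec, "seq", None) or rec[1])
        c = composition_record(seq_id, seq, at_rich_threshold, stretch_min_lengths)
        row = {
            "id": c.id, "length": c.length, "gc_percent": c.gc_percent,
            "at_percent": c.at_percent, "at_rich": c.at_rich,
            "longest_gc_stretch": c.longest_gc_stretch,
        }
        for m, n in c.gc_stretch_counts.items():
            row[f"gc_stretches_ge_{m}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def gc_bins(
    gc_values: Sequence[float] | pd.Series, edges: Sequence[float] = (40.0, 50.0, 60.0)
) -> pd.DataFrame:
    """Bin GC percentages into half-open [low, high) bands.

    The outer bands (below the first edge, at/above the last) are
    included so counts always sum to the number of records; percentages
    are rounded to 2 decimals.
    """
    edges = list(edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    values = list(pd.Series(gc_values, dtype=float))
    if not values:
        raise ValueError("gc_bins requires at least one record")
    bounds = [float("-inf")] + edges + [float("inf")]
    labels = (
        [f"<{edges[0]:g}"]
        + [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f">={edges[-1]:g}"]
    )
    counts = [0] * len(labels)
    for v in values:
        for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            if lo <= v < hi:
                counts[k] += 1
                break
    total = len(values)
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "percent": [round(100.0 * c / total, 2) for c in counts],
        }
    )
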