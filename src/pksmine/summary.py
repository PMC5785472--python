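"""BGC landscape statistics over a cluster coordinate table.

Occupancy merges overlapping intervals before summing (coverage semantics —
the only convention that cannot double-count), with inclusive spans
``to - from + 1``.  The genome fraction is rounded to one decimal percent;
the megabase total is truncated at two decimals, matching how occupancy
totals are conventionally printed (a truncated total never overstates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_model import ClusterTable

__all__ = ["OccupancySummary", "TypeGroupCount", "occupancy", "count_by_type", "merge_intervals"]


@dataclass(frozen=True)
class OccupancySummary:
    n_clusters: int
    total_bp: int
    total_mb: float  # truncated, 2 decimals
    fraction_pct: float  # rounded, 1 decimal
    genome_length: int


@dataclass(frozen=True)
class TypeGroupCount:
    group: str
    count: int
    cluster_ids: tuple[int, ...]


def merge_intervals(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(pairs):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def occupancy(table: ClusterTable) -> OccupancySummary:
    """Total genomic span covered by the clusters and its genome fraction."""
    if not table.intervals:
        raise ValueError("occupancy of an empty cluster table is undefined")
    for iv in table.intervals:
        if iv.to_bp > table.genome_length:
            raise ValueError(
                f"cluster {iv.cluster_id} exceeds the genome length"
            )
    merged = merge_intervals([(iv.from_bp, iv.to_bp) for iv in table.intervals])
    total_bp = sum(end - start + 1 for start, end in merged)
    return OccupancySummary(
        n_clusters=len(table.intervals),
        total_bp=total_bp,
        total_mb=math.floor(total_bp / 1e6 * 100) / 100,
        fraction_pct=round(100 * total_bp / table.genome_length, 1),
        genome_length=table.genome_length,
    )


def count_by_type(
    table: ClusterTable, type_groups: Mapping[str, Sequence[str]]
) -> dict[str, TypeGroupCount]:
    """Count clusters per named group by case-insensitive substring match.

    A cluster counts toward a group when any of the group's substrings
    occurs in its product type; one cluster may count toward several
    groups.  Matched cluster ids are returned for auditability.
    """
    out: dict[str, TypeGroupCount] = {}
    for group, substrings in type_groups.items():
        if not substrings:
            raise ValueError(f"type group {group!r} has no substrings")
        needles = [s.lower() for s in substrings]
        ids = tuple(
            iv.cluster_id
            for iv in table.intervals
            if any(n in iv.product_type.lower() for n in needles)
        )
        out[group] = TypeGroupCount(group=group, count=len(ids), cluster_ids=ids)
    return out
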