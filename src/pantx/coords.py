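"""Centralized coordinate conventions.

GFF3 is 1-based inclusive at every external interface; internally intervals
are 0-based half-open. All conversions go through these two functions so the
off-by-one surface is a single, tested place.
"""

from __future__ import annotations


def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start0, end0)."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval [{start}, {end}]")
    return start - 1, end


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start, end]."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid half-open interval [{start0}, {end0})")
    return start0 + 1, end0


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap length of two 0-based half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of a set of 0-based half-open intervals."""
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def interval_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals into disjoint sorted intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
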