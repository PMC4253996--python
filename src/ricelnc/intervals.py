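"""Interval arithmetic on half-open genomic intervals."""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

from .types import GenomicInterval


def interval_overlap(
    a: GenomicInterval, b: GenomicInterval, stranded: bool = False
) -> int:
    """Overlap length in bases between two intervals.

    Different chromosomes overlap by 0 bases (not an error). With
    ``stranded=True`` both strands must be known and equal for a non-zero
    overlap; comparing an unstranded interval strandedly raises.
    """
    if a.chrom != b.chrom:
        return 0
    if stranded:
        if a.strand == "." or b.strand == ".":
            raise ValueError("stranded overlap requires both strands known")
        if a.strand != b.strand:
            return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bases between two intervals on the same chromosome.

    0 if they overlap or are book-ended (half-open adjacency)."""
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def merge_intervals(
    intervals: Iterable[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """Union of (start, end) pairs as a sorted list of disjoint runs."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect_length(
    a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]
) -> int:
    """Total length of the base-level intersection of two interval sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total
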