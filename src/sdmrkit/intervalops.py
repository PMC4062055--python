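"""Vectorized interval-set primitives (merge, membership, overlap counting).

These back every intersection rule in the pipeline; bedtools-style
semantics on 0-based half-open coordinates.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import GenomicInterval

__all__ = ["merge_intervals", "MergedSet", "overlaps_any", "overlap_bp", "total_bp"]


class MergedSet:
    """Per-chromosome sorted, merged interval arrays for fast queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            starts, ends = [], []
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:  # touching intervals merge (no 0-length gaps)
                    cur_e = max(cur_e, e)
                else:
                    starts.append(cur_s)
                    ends.append(cur_e)
                    cur_s, cur_e = s, e
            starts.append(cur_s)
            ends.append(cur_e)
            self._data[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    def contains_overlap(self, iv: GenomicInterval) -> bool:
        """True iff >= 1 bp of ``iv`` falls inside the merged set."""
        return self.overlap_bp(iv) > 0

    def overlap_bp(self, iv: GenomicInterval) -> int:
        if iv.chrom not in self._data:
            return 0
        starts, ends = self._data[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if lo >= hi:
            return 0
        return int(
            np.sum(
                np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
            )
        )

    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self._data.values()))

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in self._data:
            starts, ends = self._data[chrom]
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint merged spans."""
    ivs = list(intervals)
    if not ivs:
        return []
    return MergedSet(ivs).intervals()


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask: query i shares >= 1 bp with at least one subject."""
    queries = list(queries)
    if not queries:
        return np.zeros(0, dtype=bool)
    subjects = list(subjects)
    if not subjects:
        return np.zeros(len(queries), dtype=bool)
    merged = MergedSet(subjects)
    return np.array([merged.contains_overlap(q) for q in queries], dtype=bool)


def overlap_bp(query: GenomicInterval, subjects: Sequence[GenomicInterval]) -> int:
    """Total bp of ``query`` covered by the union of ``subjects``."""
    subjects = list(subjects)
    if not subjects:
        return 0
    return MergedSet(subjects).overlap_bp(query)


def total_bp(intervals: Sequence[GenomicInterval]) -> int:
    """bp length of the merged union."""
    intervals = list(intervals)
    if not intervals:
        return 0
    return MergedSet(intervals).total_bp()
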