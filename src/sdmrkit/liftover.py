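"""Chain-based coordinate liftover between genome builds.

Implements liftOver-style region mapping with a ``minMatch`` mapped-base
threshold (inclusive, >=), split-hit rejection, a reciprocal (back-lift)
filter, and blacklist exclusion. All mapping is exact per-base arithmetic
through the chain's ungapped segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Chain, ChainSet, GenomicInterval
from .intervalops import MergedSet

__all__ = [
    "MappedInterval",
    "liftover",
    "liftover_many",
    "reciprocal_filter",
    "exclude_blacklist",
]


@dataclass(frozen=True)
class MappedInterval:
    """Result of lifting one interval: target span (if any), mapped-base
    fraction, and a status in {mapped, low_match, split, unmapped}."""

    source: GenomicInterval
    target: GenomicInterval | None
    mapped_fraction: float
    status: str


def _chain_map(interval: GenomicInterval, chain: Chain):
    """Mapped-base count and min/max forward target coords for one chain."""
    segs = chain.segments()
    if len(segs) == 0:
        return 0, None, None
    src_s = segs[:, 0]
    tgt_s = segs[:, 1]
    size = segs[:, 2]
    ov_lo = np.maximum(interval.start, src_s)
    ov_hi = np.minimum(interval.end, src_s + size)
    ov = ov_hi - ov_lo
    hit = ov > 0
    if not hit.any():
        return 0, None, None
    mapped = int(ov[hit].sum())
    # target coords of overlapped run starts/ends in chain orientation
    t_lo = tgt_s[hit] + (ov_lo[hit] - src_s[hit])
    t_hi = t_lo + ov[hit]  # exclusive
    if chain.target_strand == "-":
        # chain target coords count along the reverse strand
        fwd_lo = chain.target_size - t_hi  # inclusive forward start
        fwd_hi = chain.target_size - t_lo  # exclusive forward end
        return mapped, int(fwd_lo.min()), int(fwd_hi.max())
    return mapped, int(t_lo.min()), int(t_hi.max())


def liftover(
    interval: GenomicInterval, chains: ChainSet, min_match: float = 0.7
) -> MappedInterval:
    """Lift one interval through a chain set.

    The interval maps iff all its mappable bases fall in a single chain
    (multi-chain hits are ``split`` failures, mirroring region-mode
    liftOver) and the mapped-base fraction is >= ``min_match``. The target
    span is the [min, max+1) envelope of mapped target positions,
    reported in forward-strand coordinates.
    """
    hits = []
    for chain in chains.by_source_chrom(interval.chrom):
        mapped, t_lo, t_hi = _chain_map(interval, chain)
        if mapped > 0:
            hits.append((mapped, t_lo, t_hi, chain))
    if not hits:
        return MappedInterval(interval, None, 0.0, "unmapped")
    if len(hits) > 1:
        frac = sum(h[0] for h in hits) / len(interval)
        return MappedInterval(interval, None, frac, "split")
    mapped, t_lo, t_hi, chain = hits[0]
    frac = mapped / len(interval)
    target = GenomicInterval(
        chain.target_chrom, t_lo, t_hi, name=interval.name, strand="."
    )
    status = "mapped" if frac >= min_match else "low_match"
    return MappedInterval(interval, target, frac, status)


def liftover_many(
    intervals: Iterable[GenomicInterval], chains: ChainSet, min_match: float = 0.7
) -> list[MappedInterval]:
    return [liftover(iv, chains, min_match=min_match) for iv in intervals]


def reciprocal_filter(
    intervals: Sequence[GenomicInterval],
    chain_fwd: ChainSet,
    chain_rev: ChainSet,
    min_match: float = 0.7,
    strict: bool = False,
) -> list[GenomicInterval]:
    """Keep intervals that lift forward, lift back, and land on their
    original location.

    "Original location" means >= 1 bp overlap with the source interval
    (the pipeline's universal intersection convention); ``strict=True``
    demands exact coordinate equality instead.
    """
    retained = []
    for iv in intervals:
        fwd = liftover(iv, chain_fwd, min_match=min_match)
        if fwd.status != "mapped":
            continue
        back = liftover(fwd.target, chain_rev, min_match=min_match)
        if back.status != "mapped":
            continue
        if strict:
            ok = (
                back.target.chrom == iv.chrom
                and back.target.start == iv.start
                and back.target.end == iv.end
            )
        else:
            ok = back.target.overlaps(iv)
        if ok:
            retained.append(iv)
    return retained


def exclude_blacklist(
    intervals: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop every interval sharing >= 1 bp with any blacklisted region."""
    intervals = list(intervals)
    blacklist = list(blacklist)
    if not blacklist:
        return intervals
    merged = MergedSet(blacklist)
    return [iv for iv in intervals if not merged.contains_overlap(iv)]
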