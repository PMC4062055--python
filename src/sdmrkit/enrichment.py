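"""Genomic feature enrichment: island/shore construction, fractional
overlap counting, per-Mb densities, chi-square and shuffle-control
enrichment, point overlaps, and sequence CpG density."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency, fisher_exact

from .core import GenomicInterval
from .intervalops import MergedSet, merge_intervals, total_bp

__all__ = [
    "FeatureSet",
    "EnrichmentResult",
    "make_shores",
    "count_overlaps",
    "density_per_mb",
    "chi2_enrichment",
    "shuffle_control",
    "point_overlap",
    "cpg_density",
]


@dataclass
class FeatureSet:
    """A named annotation track; ``total_bp`` is the merged-union length
    (computed, never taken on trust)."""

    name: str
    intervals: list

    @property
    def total_bp(self) -> int:
        return total_bp(self.intervals)

    def merged(self) -> MergedSet:
        return MergedSet(self.intervals)


@dataclass
class EnrichmentResult:
    observed: float
    expected: float
    ratio: float | None
    statistic: float | None
    p_value: float
    method: str  # "chi2" | "fisher" | "shuffle"
    empirical_p: float | None = None


def make_shores(
    islands: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    flank: int = 2000,
) -> FeatureSet:
    """CpG-island shores: the ±``flank`` bp around each island, minus all
    island bp, clipped to chromosome bounds, merged."""
    merged_islands = merge_intervals(islands)
    island_set = MergedSet(merged_islands) if merged_islands else None
    raw = []
    for iv in merged_islands:
        size = chrom_sizes.get(iv.chrom)
        lo = max(0, iv.start - flank)
        hi = iv.end + flank if size is None else min(size, iv.end + flank)
        if lo < iv.start:
            raw.append(GenomicInterval(iv.chrom, lo, iv.start))
        if iv.end < hi:
            raw.append(GenomicInterval(iv.chrom, iv.end, hi))
    # subtract island bp from the merged flank union
    shores = []
    for iv in merge_intervals(raw):
        if island_set is None:
            shores.append(iv)
            continue
        cuts = [iv.start, iv.end]
        for other in merged_islands:
            if other.chrom != iv.chrom:
                continue
            if other.start < iv.end and other.end > iv.start:
                cuts.extend((max(other.start, iv.start), min(other.end, iv.end)))
        cuts = sorted(set(cuts))
        for lo, hi in zip(cuts, cuts[1:]):
            if hi > lo:
                mid = GenomicInterval(iv.chrom, lo, hi)
                if island_set.overlap_bp(mid) == 0:
                    shores.append(mid)
    return FeatureSet("shores", merge_intervals(shores))


def count_overlaps(
    regions: list[GenomicInterval],
    feature: FeatureSet | list,
    min_fraction: float = 0.5,
) -> int:
    """Number of regions whose overlap with the feature union is >=
    ``min_fraction`` of the REGION length (inclusive; bedtools ``-f``
    semantics on the query). ``min_fraction=0`` counts any >= 1 bp
    overlap."""
    intervals = feature.intervals if isinstance(feature, FeatureSet) else list(feature)
    if not regions or not intervals:
        return 0
    merged = MergedSet(intervals)
    n = 0
    for r in regions:
        ov = merged.overlap_bp(r)
        if ov == 0:
            continue
        if min_fraction <= 0 or ov / len(r) >= min_fraction:
            n += 1
    return n


def density_per_mb(count: int, feature_total_bp: float) -> float:
    """Regions per megabase of feature sequence."""
    if feature_total_bp <= 0:
        raise ValueError("feature size must be positive")
    return count / (feature_total_bp / 1e6)


def chi2_enrichment(
    k_regions: int, n_regions: int, k_background: int, n_background: int
) -> EnrichmentResult:
    """2x2 enrichment test: k-of-n in the region set versus the background.

    Pearson chi-square without continuity correction; when any expected
    cell is < 5 Fisher's exact test is used instead and flagged via
    ``method``."""
    if n_regions <= 0 or n_background <= 0:
        raise ValueError("set sizes must be positive")
    if not (0 <= k_regions <= n_regions and 0 <= k_background <= n_background):
        raise ValueError("need 0 <= k <= n on both sides")
    table = np.array(
        [
            [k_regions, n_regions - k_regions],
            [k_background, n_background - k_background],
        ],
        dtype=float,
    )
    p_bg = k_background / n_background
    expected_k = p_bg * n_regions
    ratio = (k_regions / n_regions) / p_bg if p_bg > 0 else None
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    exp = row @ col / table.sum()
    if (exp < 5).any():
        _, p = fisher_exact(table.astype(int))
        return EnrichmentResult(k_regions, expected_k, ratio, None, float(p), "fisher")
    if (table.sum(axis=0) == 0).any() or ratio == 1.0:
        # identical proportions: chi2 statistic is exactly 0
        return EnrichmentResult(k_regions, expected_k, ratio, 0.0, 1.0, "chi2")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return EnrichmentResult(k_regions, expected_k, ratio, float(stat), float(p), "chi2")


def shuffle_control(
    regions: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    feature: FeatureSet,
    n_controls: int = 100,
    seed: int = 0,
    blacklist: list | None = None,
    min_fraction: float = 0.0,
    max_tries: int = 200,
) -> EnrichmentResult:
    """Empirical enrichment against position-shuffled controls.

    Each control set preserves the region count and the exact length
    multiset; positions are uniform over the genome, non-overlapping,
    excluding the blacklist. The ratio is observed overlap count / mean
    control overlap count, with empirical p = (r + 1) / (n_controls + 1)
    where r counts controls >= observed."""
    observed = count_overlaps(regions, feature, min_fraction=min_fraction)
    rng = np.random.default_rng(seed)
    lengths = [len(r) for r in regions]
    chroms = list(chrom_sizes)
    blk = MergedSet(blacklist) if blacklist else None
    control_counts = []
    for _ in range(n_controls):
        placed: list[GenomicInterval] = []
        for length in lengths:
            ok = False
            for _t in range(max_tries):
                chrom = chroms[int(rng.integers(len(chroms)))]
                size = chrom_sizes[chrom]
                if size <= length:
                    continue
                start = int(rng.integers(0, size - length))
                cand = GenomicInterval(chrom, start, start + length)
                if blk is not None and blk.contains_overlap(cand):
                    continue
                if any(cand.overlaps(p) for p in placed):
                    continue
                placed.append(cand)
                ok = True
                break
            if not ok:
                raise RuntimeError("could not place shuffled control regions")
        control_counts.append(count_overlaps(placed, feature, min_fraction=min_fraction))
    mean_control = float(np.mean(control_counts))
    ratio = observed / mean_control if mean_control > 0 else None
    r = int(np.sum(np.asarray(control_counts) >= observed))
    emp_p = (r + 1) / (n_controls + 1)
    return EnrichmentResult(
        observed, mean_control, ratio, None, emp_p, "shuffle", empirical_p=emp_p
    )


def point_overlap(
    regions: list[GenomicInterval], positions: list[GenomicInterval]
) -> dict:
    """Overlap between regions and 1-bp positions, counted both ways.

    Returns the number of region/position hits and the hit fractions of
    each side (as proportions; multiply by 100 to report percent)."""
    if not regions or not positions:
        return {
            "regions_hit": 0,
            "positions_hit": 0,
            "region_fraction": 0.0,
            "position_fraction": 0.0,
        }
    pos_set = MergedSet(positions)
    reg_set = MergedSet(regions)
    regions_hit = sum(1 for r in regions if pos_set.contains_overlap(r))
    positions_hit = sum(1 for p in positions if reg_set.contains_overlap(p))
    return {
        "regions_hit": regions_hit,
        "positions_hit": positions_hit,
        "region_fraction": regions_hit / len(regions),
        "position_fraction": positions_hit / len(positions),
    }


def cpg_density(sequence: str) -> float:
    """Percent CpG density: 100 x (overlapping CG dinucleotides) /
    (length - 1)."""
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 bp")
    seq = sequence.upper()
    count = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    return 100.0 * count / (len(seq) - 1)
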