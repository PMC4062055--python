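"""Fragment filtering, binned coverage tracks, and cross-library
normalization for MeDIP-seq style fragment data.

Filtering mirrors standard MeDIP post-alignment hygiene: drop fragments
with mapping quality < 10, keep only correctly paired fragments, and
collapse PCR duplicates (identical chrom/start/end) to a single fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FragmentSet",
    "CoverageTrack",
    "filter_fragments",
    "normalize_to_reference",
    "rpm_track",
    "fragments_in_region",
    "MIN_QUALITY",
]

MIN_QUALITY = 10

FRAGMENT_COLUMNS = ["chrom", "start", "end", "quality", "proper_pair"]


@dataclass
class FragmentSet:
    """Filtered fragments of one species' library.

    ``frame`` has columns chrom/start/end/quality (0-based half-open);
    ``total_retained`` is the library size used as the normalization
    denominator.
    """

    species: str
    frame: pd.DataFrame

    @property
    def total_retained(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)


def filter_fragments(
    raw: pd.DataFrame, species: str = "", min_quality: int = MIN_QUALITY
) -> FragmentSet:
    """Apply the three filtering rules in order, preserving input order.

    1. discard fragments not forming a correctly aligned pair;
    2. discard fragments with alignment quality < ``min_quality``;
    3. within each duplicate group (identical chrom/start/end) keep
       exactly one fragment (the first seen).
    """
    df = raw
    if "proper_pair" in df.columns:
        df = df[df["proper_pair"].astype(bool)]
    df = df[df["quality"] >= min_quality]
    df = df.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    return FragmentSet(species, df.reset_index(drop=True))


def normalize_to_reference(reads: float, species_total: int, reference_total: int) -> float:
    """Scale a raw count onto the reference library:
    (reads / species_total) * reference_total."""
    if species_total <= 0:
        raise ValueError("species_total must be positive")
    return reads / species_total * reference_total


@dataclass
class CoverageTrack:
    """Fragment-midpoint counts in fixed-width bins tiling each chromosome."""

    bin_width: int
    counts: dict[str, np.ndarray]
    library_total: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def rpm(self) -> dict[str, np.ndarray]:
        """Reads-per-million normalized counts per bin."""
        if self.library_total == 0:
            return {c: np.zeros_like(v, dtype=float) for c, v in self.counts.items()}
        return {c: v * 1e6 / self.library_total for c, v in self.counts.items()}

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))


def rpm_track(
    fragments: FragmentSet, bin_width: int, chrom_sizes: dict[str, int]
) -> CoverageTrack:
    """Bin fragment midpoints into a coverage track.

    Midpoints of full fragments are equivalent to shifting each read by
    half the fragment length toward its mate.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts: dict[str, np.ndarray] = {}
    df = fragments.frame
    mid = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    chroms = df["chrom"].to_numpy()
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_width)
        sel = mid[chroms == chrom]
        sel = np.clip(sel // bin_width, 0, n_bins - 1)
        counts[chrom] = np.bincount(sel, minlength=n_bins).astype(np.int64)
    return CoverageTrack(
        bin_width=bin_width,
        counts=counts,
        library_total=fragments.total_retained,
        chrom_sizes=dict(chrom_sizes),
    )


def fragments_in_region(fragments: FragmentSet, chrom: str, start: int, end: int) -> int:
    """Count fragments whose midpoint falls in [start, end)."""
    df = fragments.frame
    sel = df["chrom"] == chrom
    mid = (df.loc[sel, "start"].to_numpy() + df.loc[sel, "end"].to_numpy()) // 2
    return int(np.count_nonzero((mid >= start) & (mid < end)))
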