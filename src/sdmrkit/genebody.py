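"""Gene-body methylation scoring and differential ranking.

Links promoter-CpG-island s-DMRs to transcripts, scores each transcript's
exons per species with the transformed-p peak score, and ranks transcripts
by the human-versus-outgroup differential — the step that surfaces loci
with inverse promoter/gene-body methylation changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import GenomicInterval, ScoredPeak
from .intervalops import MergedSet, overlaps_any

__all__ = [
    "GeneModel",
    "RankedRecord",
    "promoter_sdmr_transcripts",
    "exon_score",
    "differentials",
    "fold_ratio",
    "rank_records",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A transcript: promoter (TSS-anchored), ordered exons, optional
    associated 5' CpG island."""

    transcript_id: str
    gene_name: str
    strand: str
    promoter: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cpg_island_id: str | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: exons must be ordered and non-overlapping"
                )


@dataclass(frozen=True)
class RankedRecord:
    """Per-transcript exon peak scores and their differentials."""

    transcript_id: str
    score_human: float
    score_chimp: float
    score_macaque: float
    diff_hc: float
    diff_hm: float
    diff_havg: float
    fold: float | None


def promoter_sdmr_transcripts(
    sdmr_intervals: list[GenomicInterval],
    genes: list[GeneModel],
    islands: list[GenomicInterval],
) -> list[GeneModel]:
    """Transcripts whose 5' promoter CpG island overlaps (>= 1 bp) an s-DMR.

    The promoter region tested is the TSS-anchored promoter intersected
    with its associated CpG island when one is present. A bidirectional
    promoter island carrying one s-DMR returns every transcript anchored
    on it.
    """
    if not sdmr_intervals:
        return []
    sdmr_set = MergedSet(sdmr_intervals)
    island_by_id = {iv.name: iv for iv in islands}
    out = []
    for gene in genes:
        region = gene.promoter
        if gene.cpg_island_id is not None and gene.cpg_island_id in island_by_id:
            island = island_by_id[gene.cpg_island_id]
            lo = max(region.start, island.start)
            hi = min(region.end, island.end)
            if lo >= hi:
                continue
            region = GenomicInterval(region.chrom, lo, hi)
        if sdmr_set.contains_overlap(region):
            out.append(gene)
    return out


def exon_score(exons: list[GenomicInterval], peaks: list[ScoredPeak]) -> float:
    """Maximum transformed-p peak score among peaks overlapping (>= 1 bp)
    any exon; 0.0 when no peak overlaps (absence of signal scores zero)."""
    if not exons or not peaks:
        return 0.0
    best = 0.0
    exon_set = MergedSet(exons)
    for peak in peaks:
        if exon_set.contains_overlap(peak.interval) and peak.score > best:
            best = peak.score
    return best


def differentials(score_h: float, score_c: float, score_m: float):
    """(H - C, H - M, H - mean(C, M)); exact arithmetic, no rounding."""
    return (
        score_h - score_c,
        score_h - score_m,
        score_h - (score_c + score_m) / 2.0,
    )


def fold_ratio(score_h: float, score_c: float, score_m: float) -> float | None:
    """H / mean(C, M); None (reported NA) when the outgroup mean is zero."""
    denom = (score_c + score_m) / 2.0
    if denom == 0:
        return None
    return score_h / denom


def make_record(
    transcript_id: str, score_h: float, score_c: float, score_m: float
) -> RankedRecord:
    d_hc, d_hm, d_havg = differentials(score_h, score_c, score_m)
    return RankedRecord(
        transcript_id, score_h, score_c, score_m, d_hc, d_hm, d_havg,
        fold_ratio(score_h, score_c, score_m),
    )


def rank_records(records: list[RankedRecord], sdmr_class: str) -> pd.DataFrame:
    """Order transcripts by the H - mean(C, M) differential.

    For the hypomethylated-promoter set the most human-elevated gene body
    comes first (descending); for the hypermethylated-promoter set the
    order is ascending. Ties break lexicographically on transcript id.
    """
    if sdmr_class not in ("hypo", "hyper"):
        raise ValueError(f"unknown s-DMR class {sdmr_class!r}")
    df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "human": [r.score_human for r in records],
            "chimpanzee": [r.score_chimp for r in records],
            "macaque": [r.score_macaque for r in records],
            "diff_hc": [r.diff_hc for r in records],
            "diff_hm": [r.diff_hm for r in records],
            "diff_havg": [r.diff_havg for r in records],
            "fold": [r.fold for r in records],
        }
    )
    ascending = sdmr_class == "hyper"
    df = df.sort_values(
        ["diff_havg", "transcript_id"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
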