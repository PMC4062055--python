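"""Species-specific DMR calling by three-way peak triangulation.

Hypomethylated (in the reference species) s-DMRs are regions where both
out-group species carry a consensus methylation peak but the reference
carries none from either caller; hypermethylated s-DMRs are reference
consensus peaks absent from both out-groups, additionally required to
survive a reciprocal liftover through each out-group genome and to avoid
the blacklist. The third species is the out-group that assigns the
lineage of the change: without it, chimpanzee-lineage changes inflate the
"human-specific" set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .core import ChainSet, GenomicInterval, ScoredPeak
from .coverage import FragmentSet, fragments_in_region, normalize_to_reference
from .intervalops import MergedSet
from .liftover import exclude_blacklist, liftover, reciprocal_filter

__all__ = [
    "SDMR",
    "PeakUniverse",
    "lift_peaks",
    "shared_nonhuman",
    "call_hypo",
    "call_hyper",
    "benchmark_sdmr_signal",
    "triangulation_gain",
]


@dataclass(frozen=True)
class SDMR:
    """A classified species-specific DMR on the reference build."""

    interval: GenomicInterval
    sdmr_class: str  # "hypo" | "hyper"
    source_peaks: tuple[str, ...] = ()

    def __post_init__(self):
        if self.sdmr_class not in ("hypo", "hyper"):
            raise ValueError(f"invalid s-DMR class {self.sdmr_class!r}")


@dataclass
class PeakUniverse:
    """All peak sets entering triangulation.

    ``caller_a``/``caller_b``/``consensus`` map species to native-build
    peaks; ``lifted_consensus`` and ``lifted_all`` hold the
    reference-build versions for the non-reference species (``lifted_all``
    is the union of both callers' peaks, lifted).
    """

    caller_a: dict = field(default_factory=dict)
    caller_b: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    lifted_consensus: dict = field(default_factory=dict)
    lifted_all: dict = field(default_factory=dict)


def lift_peaks(
    peaks: list[ScoredPeak], chains: ChainSet, min_match: float = 0.7
) -> list[ScoredPeak]:
    """Lift peaks to the reference build, dropping failures.

    Scores are preserved; names carry native-peak provenance; the summit
    is re-clipped into the (possibly shorter) lifted span.
    """
    out = []
    for p in peaks:
        m = liftover(p.interval, chains, min_match=min_match)
        if m.status != "mapped":
            continue
        tgt = m.target
        out.append(
            ScoredPeak(
                GenomicInterval(tgt.chrom, tgt.start, tgt.end, name=p.interval.name),
                score=p.score,
                summit=min(p.summit, len(tgt) - 1),
                caller=p.caller,
            )
        )
    return out


def shared_nonhuman(
    chimp_lifted: list[ScoredPeak],
    macaque_lifted: list[ScoredPeak],
    min_overlap: int = 1,
) -> list[ScoredPeak]:
    """Chimpanzee consensus peaks (reference coordinates) confirmed by
    >= 1 bp overlap with a macaque lifted consensus peak. The chimpanzee
    peak location defines the coordinates."""
    if not chimp_lifted or not macaque_lifted:
        return []
    mac = MergedSet(p.interval for p in macaque_lifted)
    return [p for p in chimp_lifted if mac.overlap_bp(p.interval) >= min_overlap]


def call_hypo(
    shared: list[ScoredPeak],
    human_a: list[ScoredPeak],
    human_b: list[ScoredPeak],
) -> list[SDMR]:
    """Shared out-group peaks with no reference peak from either caller:
    reference-hypomethylated s-DMRs (coordinates = lifted chimpanzee peak)."""
    human_all = [p.interval for p in human_a] + [p.interval for p in human_b]
    blocked = MergedSet(human_all) if human_all else None
    out = []
    for p in shared:
        if blocked is not None and blocked.contains_overlap(p.interval):
            continue
        iv = GenomicInterval(
            p.interval.chrom, p.interval.start, p.interval.end,
            name=f"hypo_{len(out):05d}",
        )
        out.append(SDMR(iv, "hypo", source_peaks=(p.interval.name,)))
    return out


def call_hyper(
    human_consensus: list[ScoredPeak],
    chimp_all_lifted: list[ScoredPeak],
    macaque_all_lifted: list[ScoredPeak],
    chains: dict,
    blacklist: list[GenomicInterval],
    min_match: float = 0.7,
) -> list[SDMR]:
    """Reference consensus peaks absent from both out-groups.

    Pipeline order: (1) drop any reference peak overlapping (>= 1 bp) a
    lifted peak of either out-group (either caller); (2) reciprocal
    back-lift filter through each out-group genome — a candidate must
    pass for BOTH species; (3) blacklist exclusion. ``chains`` maps
    (src, tgt) species pairs to ChainSets.
    """
    nonhuman = [p.interval for p in chimp_all_lifted] + [
        p.interval for p in macaque_all_lifted
    ]
    blocked = MergedSet(nonhuman) if nonhuman else None
    candidates = [
        p for p in human_consensus
        if blocked is None or not blocked.contains_overlap(p.interval)
    ]
    intervals = [p.interval for p in candidates]
    for sp in ("chimpanzee", "macaque"):
        intervals = reciprocal_filter(
            intervals, chains[("human", sp)], chains[(sp, "human")], min_match=min_match
        )
    intervals = exclude_blacklist(intervals, blacklist)
    out = []
    for iv in intervals:
        named = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"hyper_{len(out):05d}")
        out.append(SDMR(named, "hyper", source_peaks=(iv.name,)))
    return out


def benchmark_sdmr_signal(
    sdmrs: list[SDMR],
    fragments: dict[str, FragmentSet],
    chains: dict,
    min_match: float = 0.7,
    min_n: int = 5,
) -> dict:
    """Check that called s-DMRs carry the expected raw-signal asymmetry.

    For each s-DMR, fragment counts are taken in each species' NATIVE
    coordinates (the reference interval lifted out through the chains)
    and normalized onto the reference library
    ((reads / species_total) * reference_total). Per class, the
    distributions of (n_H - n_C) and (n_H - n_M) are compared with
    (n_C - n_M) by two-sided Mann-Whitney tests: hyper classes should sit
    above the out-group contrast, hypo classes below it.
    """
    ref_total = fragments["human"].total_retained
    report: dict = {}
    by_class: dict[str, list] = {"hypo": [], "hyper": []}
    for s in sdmrs:
        by_class[s.sdmr_class].append(s)
    for cls, members in by_class.items():
        if len(members) < min_n:
            report[cls] = {"n": len(members), "status": "insufficient n"}
            continue
        rows = []
        for s in members:
            counts = {}
            ok = True
            for sp in ("human", "chimpanzee", "macaque"):
                if sp == "human":
                    native = s.interval
                else:
                    m = liftover(s.interval, chains[("human", sp)], min_match=min_match)
                    if m.status != "mapped":
                        ok = False
                        break
                    native = m.target
                raw = fragments_in_region(
                    fragments[sp], native.chrom, native.start, native.end
                )
                counts[sp] = normalize_to_reference(
                    raw, fragments[sp].total_retained, ref_total
                )
            if ok:
                rows.append(counts)
        d_hc = np.array([r["human"] - r["chimpanzee"] for r in rows])
        d_hm = np.array([r["human"] - r["macaque"] for r in rows])
        d_cm = np.array([r["chimpanzee"] - r["macaque"] for r in rows])
        entry = {"n": len(rows), "status": "ok"}
        for label, diff in (("HC_vs_CM", d_hc), ("HM_vs_CM", d_hm)):
            if np.ptp(diff) == 0 and np.ptp(d_cm) == 0 and np.all(diff == d_cm):
                entry[label] = {"p": 1.0, "note": "degenerate: no differences"}
                continue
            stat, p = mannwhitneyu(diff, d_cm, alternative="two-sided")
            entry[label] = {"p": float(p), "U": float(stat)}
        entry["median_H_minus_C"] = float(np.median(d_hc))
        entry["median_H_minus_M"] = float(np.median(d_hm))
        entry["median_C_minus_M"] = float(np.median(d_cm))
        report[cls] = entry
    return report


def triangulation_gain(two_species_calls, triangulated_calls) -> float | None:
    """Relative inflation of the two-species call set over the
    triangulated set: (|two-species| - |triangulated|) / |triangulated|.
    None (NA) when the triangulated set is empty."""
    n_two, n_tri = len(two_species_calls), len(triangulated_calls)
    if n_tri == 0:
        return None
    return (n_two - n_tri) / n_tri
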