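"""Synthetic three-species system with planted methylation truth.

Generates a reference ("human") genome plus two derived genomes
("chimpanzee", "macaque") obtained by substitutions and indels, exact
chain files built from the edit log, CpG islands, gene models, repeat and
blacklist annotations, a planted per-species methylation landscape, and
MeDIP-like fragment libraries whose local enrichment tracks
methylated-CpG content. Every downstream stage of the pipeline is
testable against the planted truth without any external data.

All randomness derives from one master seed through named substreams, so
a fixed seed reproduces every output byte-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Chain, ChainSet, GenomicInterval, decode_sequence, encode_sequence
from .genebody import GeneModel
from .intervalops import MergedSet

__all__ = [
    "TrioConfig",
    "TrioResult",
    "MethylationLandscape",
    "generate_trio",
    "plant_sdmrs",
    "simulate_medip",
    "SPECIES",
    "CLASSES",
]

SPECIES = ("human", "chimpanzee", "macaque")
NONREF_SPECIES = ("chimpanzee", "macaque")
CLASSES = (
    "human_hypo",
    "human_hyper",
    "chimp_only",
    "shared_methylated",
    "unmethylated_background",
)

# RFX-like palindromic consensus used for the planted single-base
# motif-difference sites (synthetic stand-in motif).
MOTIF_EDIT_CONSENSUS = "GTTGCCATGGCAAC"


@dataclass(frozen=True)
class TrioConfig:
    """Study conditions for the synthetic trio.

    Substitution/indel rates are per bp on the branch separating each
    non-reference species from the reference (chimpanzee ~1.4% substituted,
    macaque ~6.5%, echoing primate divergence). Methylation levels are
    per-CpG methylation probabilities; MeDIP fragment sampling weight is
    1 + enrichment_factor * (methylated CpGs in the fragment).
    """

    chrom_count: int = 2
    chrom_length: int = 1_000_000
    sub_rate: dict = field(
        default_factory=lambda: {"chimpanzee": 0.014, "macaque": 0.065}
    )
    indel_rate: dict = field(
        default_factory=lambda: {"chimpanzee": 0.0005, "macaque": 0.002}
    )
    indel_mean_length: float = 3.0  # geometric
    island_count: int = 40
    island_length: tuple = (800, 1600)
    island_cpg_weight: float = 0.22  # token probability of emitting "CG"
    gene_count: int = 24
    exons_per_gene: tuple = (2, 4)
    exon_length: tuple = (250, 400)
    linked_genes: int = 3  # genes given a promoter-hypo + gene-body-hyper pairing
    repeat_count: int = 60
    repeat_length: int = 300
    repeat_subfamilies: tuple = ("AluJ", "AluS", "AluY")
    blacklist_count: int = 4
    blacklist_length: int = 2000
    planted_counts: dict = field(
        default_factory=lambda: {
            "human_hypo": 30,
            "human_hyper": 30,
            "chimp_only": 20,
            "shared_methylated": 20,
            "unmethylated_background": 20,
        }
    )
    region_length: tuple = (400, 700)
    placement_mix: dict = field(
        default_factory=lambda: {"island": 0.3, "shore": 0.3, "open": 0.4}
    )
    level_high: float = 0.85
    level_low: float = 0.005
    background_level: float = 0.005
    motif_edit_count: int = 5
    coverage: float = 30.0
    coverage_multipliers: dict = field(
        default_factory=lambda: {"human": 1.0, "chimpanzee": 1.1, "macaque": 1.2}
    )
    fraglen_mean: int = 200
    fraglen_sd: int = 30
    enrichment_factor: float = 4.0
    dup_fraction: float = 0.02
    lowq_fraction: float = 0.02
    improper_fraction: float = 0.01
    indel_margin: int = 300  # indel-free halo around planted regions
    planted_min_gap: int = 700  # spacing so peak flanks of neighbours stay apart
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.level_low < self.level_high <= 1):
            raise ValueError("require 0 <= level_low < level_high <= 1")
        for d in (self.sub_rate, self.indel_rate):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates must be >= 0")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.chrom_count)}


@dataclass
class MethylationLandscape:
    """Piecewise-constant per-species methylation probability.

    ``segments[species][chrom]`` lists (start, end, level) in that
    species' NATIVE coordinates; everywhere else the level is
    ``background``.
    """

    background: float
    segments: dict
    chrom_lengths: dict  # species -> chrom -> native length

    def levels_at(self, species: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        out = np.full(len(positions), self.background, dtype=float)
        for start, end, level in self.segments.get(species, {}).get(chrom, []):
            mask = (positions >= start) & (positions < end)
            out[mask] = level
        return out


@dataclass
class TrioResult:
    config: TrioConfig
    genomes: dict  # species -> chrom -> str
    chains: dict  # (src, tgt) -> ChainSet
    islands: list
    genes: list
    repeats: list
    blacklist: list
    truth: pd.DataFrame
    landscape: MethylationLandscape
    edit_log: dict  # species -> chrom -> DataFrame(pos, kind, length)
    motif_edits: pd.DataFrame

    def ref_to_native(self, species: str, chrom: str, pos: int) -> int:
        """Map a reference coordinate to the species' native coordinate.

        Exact for positions outside deleted segments (planted regions are
        indel-free by construction)."""
        if species == "human":
            return pos
        log = self.edit_log[species][chrom]
        indels = log[log["kind"] != "sub"]
        if indels.empty:
            return pos
        pos_arr = indels["pos"].to_numpy()
        delta = np.where(
            indels["kind"].to_numpy() == "ins",
            indels["length"].to_numpy(),
            -indels["length"].to_numpy(),
        )
        i = int(np.searchsorted(pos_arr, pos, side="right"))
        return pos + int(delta[:i].sum())


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _island_codes(rng: np.random.Generator, n: int, cpg_weight: float) -> np.ndarray:
    """CpG-enriched sequence: token stream emitting 'CG' with probability
    ``cpg_weight``, a uniform single base otherwise."""
    n_tokens = n + 8
    is_cg = rng.random(n_tokens) < cpg_weight
    singles = _random_codes(rng, n_tokens)
    parts = np.empty(2 * n_tokens, dtype=np.int8)
    pos = 0
    for i in range(n_tokens):
        if is_cg[i]:
            parts[pos] = 1  # C
            parts[pos + 1] = 2  # G
            pos += 2
        else:
            parts[pos] = singles[i]
            pos += 1
        if pos >= n:
            break
    return parts[:n]


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    length_range: tuple,
    chrom_sizes: dict,
    occupied: list,
    min_gap: int = 100,
    max_tries: int = 20000,
    what: str = "feature",
) -> list[GenomicInterval]:
    """Uniformly place n non-overlapping intervals avoiding ``occupied``."""
    chroms = list(chrom_sizes)
    placed: list[GenomicInterval] = []
    taken = list(occupied)
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} {what} regions without overlap")
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = chrom_sizes[chrom]
        if size <= length + 2 * min_gap:
            continue
        start = int(rng.integers(min_gap, size - length - min_gap))
        cand = GenomicInterval(chrom, start, start + length)
        pad = GenomicInterval(chrom, max(0, start - min_gap), start + length + min_gap)
        if any(pad.overlaps(t) for t in taken):
            continue
        placed.append(cand)
        taken.append(cand)
    return placed


def plant_sdmrs(
    config: TrioConfig,
    islands: list[GenomicInterval],
    rng: np.random.Generator | None = None,
    occupied: list | None = None,
    forced: list | None = None,
):
    """Place planted truth regions and derive the methylation landscape.

    Classes are distributed over islands, island shores and open genome
    per ``config.placement_mix``. ``forced`` entries are
    (interval, class, placement) placed verbatim before random placement
    (used for the linked promoter/gene-body fixtures). Returns the truth
    table (reference coordinates) and the reference-coordinate landscape
    segments per species.
    """
    rng = rng if rng is not None else _substream(config.seed, "plant")
    chrom_sizes = config.chrom_sizes
    occupied = list(occupied or [])
    island_set = MergedSet(islands) if islands else None
    rows = []
    taken = list(occupied)

    gap = config.planted_min_gap

    def _register(iv, cls, placement):
        h, c, m = _class_levels(cls, config.level_low, config.level_high)
        rows.append(
            {
                "region_id": f"sdmr_truth_{len(rows):04d}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "class": cls,
                "placement": placement,
                "level_human": h,
                "level_chimpanzee": c,
                "level_macaque": m,
            }
        )
        # register with a halo so neighbouring peak flanks cannot touch
        taken.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - gap),
                min(chrom_sizes[iv.chrom], iv.end + gap),
            )
        )

    for iv, cls, placement in forced or []:
        if any(iv.overlaps(t) for t in taken):
            raise RuntimeError(f"forced planted region {iv} overlaps existing feature")
        _register(iv, cls, placement)

    # remaining budget per class, interleaved so every class sees every
    # placement kind
    budget = dict(config.planted_counts)
    for row in rows:
        budget[row["class"]] = budget.get(row["class"], 0) - 1
    queue = []
    for cls in CLASSES:
        queue.extend([cls] * max(0, budget.get(cls, 0)))
    rng.shuffle(queue)
    kinds = list(config.placement_mix)
    kind_p = np.array([config.placement_mix[k] for k in kinds], dtype=float)
    kind_p = kind_p / kind_p.sum()

    free_islands = [iv for iv in islands]
    rng.shuffle(free_islands)
    free_shores: list[tuple[GenomicInterval, int]] = [
        (iv, side) for iv in islands for side in (0, 1)
    ]
    rng.shuffle(free_shores)

    for cls in queue:
        placed = None
        for _attempt in range(200):
            kind = kinds[int(rng.choice(len(kinds), p=kind_p))]
            length = int(rng.integers(config.region_length[0], config.region_length[1] + 1))
            if kind == "island" and free_islands:
                for i, isl in enumerate(free_islands):
                    if len(isl) < length + 20:
                        continue
                    off = int(rng.integers(10, len(isl) - length - 10 + 1))
                    cand = GenomicInterval(isl.chrom, isl.start + off, isl.start + off + length)
                    if not any(cand.overlaps(t) for t in taken):
                        placed = (cand, "island")
                        free_islands.pop(i)
                        break
            elif kind == "shore" and free_shores:
                isl, side = free_shores.pop()
                if side == 0:
                    hi = isl.start
                    lo = max(0, isl.start - 2000)
                else:
                    lo = isl.end
                    hi = min(chrom_sizes[isl.chrom], isl.end + 2000)
                if hi - lo >= length + 20:
                    off = int(rng.integers(0, hi - lo - length + 1))
                    cand = GenomicInterval(isl.chrom, lo + off, lo + off + length)
                    if not any(cand.overlaps(t) for t in taken) and (
                        island_set is None or not island_set.contains_overlap(cand)
                    ):
                        placed = (cand, "shore")
            else:  # open genome
                try:
                    cand = _place_nonoverlapping(
                        rng, 1, (length, length), chrom_sizes,
                        taken + (islands or []), min_gap=300, max_tries=500,
                        what="planted",
                    )[0]
                except RuntimeError:
                    cand = None
                if cand is not None:
                    placed = (cand, "open")
            if placed:
                break
        if placed is None:
            raise RuntimeError(
                f"could not place planted region of class {cls}: space exhausted"
            )
        _register(placed[0], cls, placed[1])

    truth = pd.DataFrame(rows)
    if not truth.empty:
        truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    ref_segments = {
        sp: {
            chrom: [
                (int(r.start), int(r.end), float(getattr(r, f"level_{sp}")))
                for r in truth.itertuples()
                if r.chrom == chrom
            ]
            for chrom in chrom_sizes
        }
        for sp in SPECIES
    }
    return truth, ref_segments


def _class_levels(cls: str, low: float, high: float):
    if cls == "human_hypo":
        return low, high, high
    if cls == "human_hyper":
        return high, low, low
    if cls == "chimp_only":
        return low, high, low
    if cls == "shared_methylated":
        return high, high, high
    if cls == "unmethylated_background":
        return low, low, low
    raise ValueError(f"unknown class {cls!r}")


def _sample_indels(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    rate: float,
    mean_len: float,
    forbidden: MergedSet | None,
):
    """Sorted non-overlapping indel records (pos, kind, length)."""
    n = rng.poisson(rate * chrom_len)
    if n == 0:
        return []
    pos = np.sort(rng.integers(1, chrom_len - 50, size=n))
    kinds = rng.random(n) < 0.5  # True => deletion
    # geometric with mean `mean_len` (support >= 1)
    p = 1.0 / mean_len
    lengths = rng.geometric(p, size=n)
    records = []
    last_end = -10
    for i in range(n):
        p0 = int(pos[i])
        ln = int(lengths[i])
        kind = "del" if kinds[i] else "ins"
        span_end = p0 + (ln if kind == "del" else 0)
        if p0 - last_end < 2 or span_end >= chrom_len - 10:
            continue
        probe = GenomicInterval(chrom, p0, max(span_end, p0 + 1))
        if forbidden is not None and forbidden.contains_overlap(probe):
            continue
        records.append((p0, kind, ln))
        last_end = span_end
    return records


def _apply_edits(ref: np.ndarray, subs, indels, rng: np.random.Generator):
    """Apply substitutions then indels; return (derived codes, chain blocks).

    ``subs`` is (positions, new_codes); ``indels`` sorted (pos, kind, len)
    records. Blocks are (size, dsource, dtarget) with source = reference.
    """
    seq = ref.copy()
    if len(subs[0]):
        seq[subs[0]] = subs[1]
    parts = []
    blocks = []
    cur = 0
    for p0, kind, ln in indels:
        parts.append(seq[cur:p0])
        size = p0 - cur
        if kind == "del":
            blocks.append((size, ln, 0))
            cur = p0 + ln
        else:
            blocks.append((size, 0, ln))
            parts.append(_random_codes(rng, ln))
            cur = p0
    parts.append(seq[cur:])
    blocks.append((len(seq) - cur, 0, 0))
    derived = np.concatenate(parts) if len(parts) > 1 else parts[0]
    return derived, blocks


def _chains_from_blocks(chrom, blocks, src_len, tgt_len, chain_id):
    fwd = Chain(
        score=10 * src_len, source_chrom=chrom, source_size=src_len,
        source_strand="+", source_start=0, source_end=src_len,
        target_chrom=chrom, target_size=tgt_len, target_strand="+",
        target_start=0, target_end=tgt_len,
        blocks=[tuple(b) for b in blocks], chain_id=chain_id,
    )
    rev = Chain(
        score=10 * src_len, source_chrom=chrom, source_size=tgt_len,
        source_strand="+", source_start=0, source_end=tgt_len,
        target_chrom=chrom, target_size=src_len, target_strand="+",
        target_start=0, target_end=src_len,
        blocks=[(s, dq, dt) for (s, dt, dq) in blocks], chain_id=chain_id,
    )
    fwd.validate()
    rev.validate()
    return fwd, rev


def generate_trio(config: TrioConfig) -> TrioResult:
    """Generate the full synthetic trio; see module docstring."""
    chrom_sizes = config.chrom_sizes
    rng_genome = _substream(config.seed, "genome")
    rng_features = _substream(config.seed, "features")
    rng_plant = _substream(config.seed, "plant")
    rng_edits = _substream(config.seed, "edits")

    # 1. reference genome with CpG-enriched islands
    ref_codes = {c: _random_codes(rng_genome, n) for c, n in chrom_sizes.items()}
    islands = _place_nonoverlapping(
        rng_features, config.island_count, config.island_length, chrom_sizes,
        occupied=[], min_gap=4200, what="island",
    )
    islands = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"cpgi_{i:03d}")
        for i, iv in enumerate(sorted(islands, key=lambda x: (x.chrom, x.start)))
    ]
    for iv in islands:
        ref_codes[iv.chrom][iv.start:iv.end] = _island_codes(
            rng_genome, len(iv), config.island_cpg_weight
        )

    # 2. gene models anchored on islands (promoter = TSS +/- 1 kb, TSS at
    # island center, exons downstream of the island)
    genes: list[GeneModel] = []
    gene_islands = [iv for iv in islands]
    rng_features.shuffle(gene_islands)
    island_occ = MergedSet(islands)
    exon_occupied: list[GenomicInterval] = []
    gi = 0
    while len(genes) < config.gene_count and gi < len(gene_islands):
        isl = gene_islands[gi]
        gi += 1
        tss = (isl.start + isl.end) // 2
        n_exons = int(rng_features.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        cursor = isl.end + 1200  # first exon clear of the promoter island flank
        ok = True
        for _ in range(n_exons):
            elen = int(rng_features.integers(config.exon_length[0], config.exon_length[1] + 1))
            exon = GenomicInterval(isl.chrom, cursor, cursor + elen)
            if exon.end > chrom_sizes[isl.chrom] - 100 or island_occ.contains_overlap(exon):
                ok = False
                break
            exons.append(exon)
            cursor = exon.end + int(rng_features.integers(150, 400))
        if not ok or not exons:
            continue
        tid = f"TX{len(genes):03d}-001"
        genes.append(
            GeneModel(
                transcript_id=tid,
                gene_name=f"GENE{len(genes):03d}",
                strand="+",
                promoter=GenomicInterval(isl.chrom, max(0, tss - 1000), tss + 1000),
                exons=tuple(exons),
                cpg_island_id=isl.name,
            )
        )

    # exons of NON-linked genes are kept clear of random planted regions;
    # linked genes deliberately receive a planted region in their first exon
    for i, gene in enumerate(genes):
        skip_first = i < config.linked_genes
        exon_occupied.extend(gene.exons[1:] if skip_first else gene.exons)

    # 3. linked fixtures: promoter-island hypo region + first-exon hyper
    # region for the first `linked_genes` genes (the LTB4R-like pattern)
    forced = []
    rlen = config.region_length
    for gene in genes[: config.linked_genes]:
        isl = next(iv for iv in islands if iv.name == gene.cpg_island_id)
        length = min(rlen[0], len(isl) - 20)
        mid = (isl.start + isl.end) // 2
        hypo = GenomicInterval(isl.chrom, mid - length // 2, mid - length // 2 + length)
        exon = gene.exons[0]
        hyper = GenomicInterval(exon.chrom, exon.start, exon.start + max(len(exon), rlen[0]))
        forced.append((hypo, "human_hypo", "island"))
        forced.append((hyper, "human_hyper", "open"))

    # 4. planted truth + landscape (reference coordinates); exons of
    # non-linked genes kept clear of random planted regions
    truth, ref_segments = plant_sdmrs(
        config, islands, rng=rng_plant, occupied=exon_occupied, forced=forced
    )

    # 5. motif-difference sites inside island-placed human_hypo regions:
    # consensus motif written into the reference, one central base
    # substituted on both non-reference branches
    motif_rows = []
    motif_len = len(MOTIF_EDIT_CONSENSUS)
    motif_codes = encode_sequence(MOTIF_EDIT_CONSENSUS)
    candidates = truth[(truth["class"] == "human_hypo") & (truth["placement"] == "island")]
    for r in candidates.head(config.motif_edit_count).itertuples():
        center = (r.start + r.end) // 2
        mstart = center - motif_len // 2
        ref_codes[r.chrom][mstart : mstart + motif_len] = motif_codes
        edit_off = motif_len // 2  # central position
        pos = mstart + edit_off
        old = int(ref_codes[r.chrom][pos])
        alt = (old + 2) % 4  # transversion, deterministic
        motif_rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "pos": pos,
                "motif_start": mstart,
                "ref_base": "ACGT"[old],
                "nonhuman_base": "ACGT"[alt],
            }
        )
    motif_edits = pd.DataFrame(
        motif_rows, columns=["region_id", "chrom", "pos", "motif_start", "ref_base", "nonhuman_base"]
    )

    # 6. branch edits, derived genomes, exact chains
    planted_halo = [
        GenomicInterval(
            r.chrom,
            max(0, r.start - config.indel_margin),
            min(chrom_sizes[r.chrom], r.end + config.indel_margin),
        )
        for r in truth.itertuples()
    ]
    forbidden = MergedSet(planted_halo) if planted_halo else None
    genomes = {"human": {c: decode_sequence(v) for c, v in ref_codes.items()}}
    chains: dict[tuple, list] = {}
    edit_log: dict[str, dict] = {}
    for sp in NONREF_SPECIES:
        sp_genome = {}
        fwd_chains, rev_chains = [], []
        edit_log[sp] = {}
        for ci, (chrom, L) in enumerate(chrom_sizes.items()):
            rng_sp = _substream(config.seed, f"edits:{sp}:{chrom}")
            n_sub = rng_sp.poisson(config.sub_rate[sp] * L)
            sub_pos = np.unique(rng_sp.integers(0, L, size=n_sub))
            shift = rng_sp.integers(1, 4, size=len(sub_pos)).astype(np.int8)
            sub_new = ((ref_codes[chrom][sub_pos] + shift) % 4).astype(np.int8)
            # forced motif-difference substitutions override sampled ones
            for mr in motif_rows:
                if mr["chrom"] != chrom:
                    continue
                protected = (sub_pos < mr["motif_start"]) | (
                    sub_pos >= mr["motif_start"] + motif_len
                )
                sub_pos, sub_new = sub_pos[protected], sub_new[protected]
                sub_pos = np.append(sub_pos, mr["pos"])
                sub_new = np.append(sub_new, np.int8("ACGT".index(mr["nonhuman_base"])))
            order = np.argsort(sub_pos)
            sub_pos, sub_new = sub_pos[order], sub_new[order]
            indels = _sample_indels(
                rng_sp, chrom, L, config.indel_rate[sp], config.indel_mean_length,
                forbidden,
            )
            derived, blocks = _apply_edits(
                ref_codes[chrom], (sub_pos, sub_new), indels, rng_sp
            )
            sp_genome[chrom] = decode_sequence(derived)
            fwd, rev = _chains_from_blocks(chrom, blocks, L, len(derived), ci + 1)
            fwd_chains.append(fwd)
            rev_chains.append(rev)
            log = pd.DataFrame(
                {
                    "pos": np.concatenate([sub_pos, [p for p, _, _ in indels]]).astype(np.int64),
                    "kind": ["sub"] * len(sub_pos) + [k for _, k, _ in indels],
                    "length": np.concatenate([np.ones(len(sub_pos)), [l for _, _, l in indels]]).astype(np.int64),
                }
            ).sort_values("pos", kind="mergesort").reset_index(drop=True)
            edit_log[sp][chrom] = log
        genomes[sp] = sp_genome
        chains[("human", sp)] = ChainSet(fwd_chains)
        chains[(sp, "human")] = ChainSet(rev_chains)

    # 7. repeats and blacklist (annotation only)
    repeats = _place_nonoverlapping(
        rng_features, config.repeat_count, (config.repeat_length, config.repeat_length),
        chrom_sizes, occupied=islands + list(truth_intervals(truth)), min_gap=50,
        what="repeat",
    )
    subfam = [
        config.repeat_subfamilies[int(rng_features.integers(len(config.repeat_subfamilies)))]
        for _ in repeats
    ]
    repeats = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=name)
        for iv, name in zip(repeats, subfam)
    ]
    blacklist = _place_nonoverlapping(
        rng_features, config.blacklist_count,
        (config.blacklist_length, config.blacklist_length), chrom_sizes,
        occupied=islands + list(truth_intervals(truth)) + repeats,
        min_gap=500, what="blacklist",
    )
    blacklist = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"blk_{i}")
        for i, iv in enumerate(blacklist)
    ]

    # 8. native-coordinate landscape for each species
    result = TrioResult(
        config=config, genomes=genomes, chains=chains, islands=islands,
        genes=genes, repeats=repeats, blacklist=blacklist, truth=truth,
        landscape=None, edit_log=edit_log, motif_edits=motif_edits,
    )
    segments = {sp: {c: [] for c in chrom_sizes} for sp in SPECIES}
    for r in truth.itertuples():
        for sp in SPECIES:
            level = float(getattr(r, f"level_{sp}"))
            s = result.ref_to_native(sp, r.chrom, r.start)
            e = result.ref_to_native(sp, r.chrom, r.end)
            segments[sp][r.chrom].append((s, e, level))
    result.landscape = MethylationLandscape(
        background=config.background_level,
        segments=segments,
        chrom_lengths={
            sp: {c: len(genomes[sp][c]) for c in chrom_sizes} for sp in SPECIES
        },
    )
    return result


def truth_intervals(truth: pd.DataFrame):
    for r in truth.itertuples():
        yield GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.region_id)


def simulate_medip(
    genome: dict[str, str],
    landscape: MethylationLandscape,
    species: str,
    coverage: float,
    fraglen_mean: int = 200,
    fraglen_sd: int = 30,
    enrichment_factor: float = 4.0,
    dup_fraction: float = 0.02,
    lowq_fraction: float = 0.02,
    improper_fraction: float = 0.01,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample MeDIP-like fragments for one species.

    Fragment midpoints are drawn with weight
    1 + enrichment_factor * (expected methylated-CpG content within one
    mean fragment length centered on the midpoint), where the expected
    content sums each CpG's methylation level; lengths are normal around
    ``fraglen_mean``. A configurable fraction of fragments is emitted as
    exact duplicates, assigned quality < 10, or flagged improperly paired,
    to exercise the filtering stage. Returns a DataFrame with columns
    chrom/start/end/quality/proper_pair.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    frames = []
    for chrom, seq in genome.items():
        L = len(seq)
        expected = landscape.chrom_lengths.get(species, {}).get(chrom)
        if expected is not None and expected != L:
            raise ValueError(
                f"landscape/genome length mismatch on {chrom}: {expected} != {L}"
            )
        n_frag = int(round(coverage * L / fraglen_mean))
        if n_frag == 0:
            continue
        codes = encode_sequence(seq)
        cpg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
        levels = landscape.levels_at(species, chrom, cpg)
        # expected methylated-CpG content per window: cumulative sum of
        # per-CpG methylation levels, evaluated over a mean-fragment-length
        # window centred on each candidate midpoint
        cum = np.concatenate(([0.0], np.cumsum(levels)))
        half = fraglen_mean // 2
        mids = np.arange(L, dtype=np.int64)
        lo = np.searchsorted(cpg, mids - half)
        hi = np.searchsorted(cpg, mids + half)
        meth_content = cum[hi] - cum[lo]
        weights = 1.0 + enrichment_factor * meth_content
        weights /= weights.sum()
        mid_sel = rng.choice(L, size=n_frag, replace=True, p=weights)
        lengths = np.clip(
            np.rint(rng.normal(fraglen_mean, fraglen_sd, size=n_frag)), 50, None
        ).astype(np.int64)
        starts = np.clip(mid_sel - lengths // 2, 0, None)
        ends = np.minimum(starts + lengths, L)
        starts = np.maximum(np.minimum(starts, ends - 1), 0)
        quality = np.full(n_frag, 60, dtype=np.int64)
        lowq = rng.random(n_frag) < lowq_fraction
        quality[lowq] = rng.integers(0, 10, size=int(lowq.sum()))
        proper = rng.random(n_frag) >= improper_fraction
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": ends,
                "quality": quality,
                "proper_pair": proper,
            }
        )
        n_dup = int(round(dup_fraction * n_frag))
        if n_dup:
            dup_idx = rng.choice(n_frag, size=n_dup, replace=False)
            frames.append(pd.concat([df, df.iloc[dup_idx]], ignore_index=True))
        else:
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "quality", "proper_pair"])
    return pd.concat(frames, ignore_index=True)


def simulate_trio_medip(result: TrioResult, seed_offset: int = 0) -> dict[str, pd.DataFrame]:
    """MeDIP fragment libraries for all three species of a generated trio."""
    cfg = result.config
    out = {}
    for sp in SPECIES:
        rng = _substream(cfg.seed + seed_offset, f"fragments:{sp}")
        out[sp] = simulate_medip(
            result.genomes[sp],
            result.landscape,
            sp,
            coverage=cfg.coverage * cfg.coverage_multipliers.get(sp, 1.0),
            fraglen_mean=cfg.fraglen_mean,
            fraglen_sd=cfg.fraglen_sd,
            enrichment_factor=cfg.enrichment_factor,
            dup_fraction=cfg.dup_fraction,
            lowq_fraction=cfg.lowq_fraction,
            improper_fraction=cfg.improper_fraction,
            rng=rng,
        )
    return out
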