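"""End-to-end pipeline orchestration.

Stages run in a fixed order — simulate/ingest, filter, peaks+consensus,
lift, triangulate, enrich, motifs, rank, report — and every hand-off goes
through files persisted in the run directory, so any stage can be rerun
from the previous stage's outputs and a fixed seed reproduces the whole
run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .core import GenomicInterval, ScoredPeak
from .coverage import filter_fragments, rpm_track, FragmentSet
from .enrichment import (
    FeatureSet,
    chi2_enrichment,
    count_overlaps,
    density_per_mb,
    make_shores,
    shuffle_control,
)
from .genebody import (
    GeneModel,
    exon_score,
    make_record,
    promoter_sdmr_transcripts,
    rank_records,
)
from .intervalops import overlaps_any
from .liftover import liftover
from .motifs import (
    AffinityModel,
    RegionTriplet,
    bh_adjust,
    divergence_map,
    orthologous_identity,
    region_set_pvalue,
)
from .peaks import call_peaks_poisson, call_peaks_posterior, consensus
from .synthetic import (
    SPECIES,
    TrioConfig,
    generate_trio,
    simulate_trio_medip,
    truth_intervals,
)
from .triangulate import (
    SDMR,
    call_hyper,
    call_hypo,
    benchmark_sdmr_signal,
    lift_peaks,
    shared_nonhuman,
    triangulation_gain,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_report", "STAGES"]

logger = logging.getLogger(__name__)

NONREF = ("chimpanzee", "macaque")


@dataclass
class PipelineConfig:
    """One run's complete configuration (synthetic or user-data mode)."""

    outdir: str = "sdmr_run"
    mode: str = "synthetic"
    seed: int = 0
    trio: TrioConfig = None
    # user-data mode inputs
    fragment_paths: dict = field(default_factory=dict)  # species -> TSV/BED
    chain_paths: dict = field(default_factory=dict)  # "human:chimpanzee" -> path
    island_path: str | None = None
    blacklist_path: str | None = None
    gene_path: str | None = None
    chrom_sizes_path: str | None = None
    # caller / liftover / feature parameters
    fraglen: int = 200
    bin_width: int = 50
    p_threshold: float = 1e-3
    score_convention: str = "-10log10"
    min_match: float = 0.7
    shore_flank: int = 2000
    island_min_fraction: float = 0.5
    # motif stage
    motif_file: str | None = None  # default: bundled demonstration matrices
    motif_b_draws: int = 199
    motif_max_regions: int = 30
    divergence_threshold: float = 1.0

    def __post_init__(self):
        if self.mode not in ("synthetic", "user-data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.trio is None and self.mode == "synthetic":
            self.trio = TrioConfig(seed=self.seed)
        if self.mode == "user-data":
            missing = [
                p
                for p in [
                    *self.fragment_paths.values(),
                    *self.chain_paths.values(),
                    self.island_path,
                    self.blacklist_path,
                    self.chrom_sizes_path,
                ]
                if p is not None and not Path(p).exists()
            ]
            if missing:
                raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        trio_raw = raw.pop("trio", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if trio_raw:
            base = asdict(cfg.trio) if cfg.trio else {}
            base.update(trio_raw)
            base.setdefault("seed", cfg.seed)
            cfg.trio = TrioConfig(**base)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunReport:
    counts: dict
    config_hash: str
    wallclock_s: float


def _out(cfg: PipelineConfig, *parts) -> Path:
    p = Path(cfg.outdir).joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)


def _genes_to_tsv(genes: list[GeneModel], path: Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "transcript_id": g.transcript_id,
                "gene_name": g.gene_name,
                "strand": g.strand,
                "chrom": g.promoter.chrom,
                "promoter_start": g.promoter.start,
                "promoter_end": g.promoter.end,
                "island_id": g.cpg_island_id or ".",
                "exons": ",".join(f"{e.start}-{e.end}" for e in g.exons),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _genes_from_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        exons = tuple(
            GenomicInterval(r.chrom, int(s.split("-")[0]), int(s.split("-")[1]))
            for s in str(r.exons).split(",")
        )
        genes.append(
            GeneModel(
                transcript_id=r.transcript_id,
                gene_name=r.gene_name,
                strand=r.strand,
                promoter=GenomicInterval(r.chrom, int(r.promoter_start), int(r.promoter_end)),
                exons=exons,
                cpg_island_id=None if r.island_id == "." else r.island_id,
            )
        )
    return genes


# ----------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate the trio and its fragment libraries; persist everything."""
    if cfg.mode != "synthetic":
        return stage_ingest(cfg)
    trio = generate_trio(cfg.trio)
    for sp in SPECIES:
        sio.write_fasta(_out(cfg, "genomes", f"{sp}.fa"), trio.genomes[sp])
    for (src, tgt), cs in trio.chains.items():
        sio.write_chain(_out(cfg, "chains", f"{src}_to_{tgt}.chain"), cs)
    sio.write_intervals(_out(cfg, "annot", "islands.bed"), trio.islands)
    sio.write_intervals(_out(cfg, "annot", "repeats.bed"), trio.repeats)
    sio.write_intervals(_out(cfg, "annot", "blacklist.bed"), trio.blacklist)
    _genes_to_tsv(trio.genes, _out(cfg, "annot", "genes.tsv"))
    trio.truth.to_csv(_out(cfg, "annot", "truth.tsv"), sep="\t", index=False)
    trio.motif_edits.to_csv(_out(cfg, "annot", "motif_edits.tsv"), sep="\t", index=False)
    sizes = {
        sp: {c: len(s) for c, s in trio.genomes[sp].items()} for sp in SPECIES
    }
    _write_json(_out(cfg, "chrom_sizes.json"), sizes)
    frags = simulate_trio_medip(trio)
    for sp, df in frags.items():
        df.to_csv(_out(cfg, "fragments", f"raw_{sp}.tsv"), sep="\t", index=False)
    logger.info(
        "simulate: %d islands, %d genes, %d planted regions",
        len(trio.islands), len(trio.genes), len(trio.truth),
    )


def stage_ingest(cfg: PipelineConfig) -> None:
    """User-data mode: normalize user inputs into the run layout."""
    sizes = _read_json(Path(cfg.chrom_sizes_path))
    _write_json(_out(cfg, "chrom_sizes.json"), sizes)
    for sp, path in cfg.fragment_paths.items():
        pd.read_csv(path, sep="\t").to_csv(
            _out(cfg, "fragments", f"raw_{sp}.tsv"), sep="\t", index=False
        )
    for key, path in cfg.chain_paths.items():
        src, tgt = key.split(":")
        sio.write_chain(
            _out(cfg, "chains", f"{src}_to_{tgt}.chain"), sio.read_chain(path)
        )
    sio.write_intervals(
        _out(cfg, "annot", "islands.bed"), sio.read_intervals(cfg.island_path)
    )
    blk = sio.read_intervals(cfg.blacklist_path) if cfg.blacklist_path else []
    sio.write_intervals(_out(cfg, "annot", "blacklist.bed"), blk)
    if cfg.gene_path:
        _genes_to_tsv(_genes_from_tsv(Path(cfg.gene_path)), _out(cfg, "annot", "genes.tsv"))


def stage_filter(cfg: PipelineConfig) -> None:
    totals = {}
    for sp in SPECIES:
        raw = pd.read_csv(_out(cfg, "fragments", f"raw_{sp}.tsv"), sep="\t")
        fs = filter_fragments(raw, species=sp)
        fs.frame.to_csv(_out(cfg, "fragments", f"filtered_{sp}.tsv"), sep="\t", index=False)
        totals[sp] = fs.total_retained
        logger.info("filter[%s]: %d -> %d fragments", sp, len(raw), fs.total_retained)
    _write_json(_out(cfg, "fragments", "totals.json"), totals)


def _load_fragments(cfg: PipelineConfig, sp: str) -> FragmentSet:
    df = pd.read_csv(_out(cfg, "fragments", f"filtered_{sp}.tsv"), sep="\t")
    return FragmentSet(sp, df)


def stage_peaks(cfg: PipelineConfig) -> None:
    sizes = _read_json(_out(cfg, "chrom_sizes.json"))
    for sp in SPECIES:
        fs = _load_fragments(cfg, sp)
        track = rpm_track(fs, cfg.bin_width, {c: int(n) for c, n in sizes[sp].items()})
        pois = call_peaks_poisson(
            track, cfg.fraglen, p_threshold=cfg.p_threshold,
            score_convention=cfg.score_convention,
        )
        post = call_peaks_posterior(track)
        cons = consensus(pois, post)
        sio.write_intervals(_out(cfg, "peaks", f"{sp}_poisson.bed"), pois, "scored-peak")
        sio.write_intervals(_out(cfg, "peaks", f"{sp}_posterior.bed"), post, "scored-peak")
        sio.write_intervals(_out(cfg, "peaks", f"{sp}_consensus.bed"), cons, "scored-peak")
        logger.info(
            "peaks[%s]: %d poisson, %d posterior, %d consensus",
            sp, len(pois), len(post), len(cons),
        )


def _load_peaks(cfg: PipelineConfig, name: str) -> list[ScoredPeak]:
    return sio.read_intervals(_out(cfg, "peaks", f"{name}.bed"), "scored-peak")


def _load_chains(cfg: PipelineConfig, src: str, tgt: str):
    return sio.read_chain(_out(cfg, "chains", f"{src}_to_{tgt}.chain"))


def stage_lift(cfg: PipelineConfig) -> None:
    for sp in NONREF:
        chains = _load_chains(cfg, sp, "human")
        cons = _load_peaks(cfg, f"{sp}_consensus")
        both = _load_peaks(cfg, f"{sp}_poisson") + _load_peaks(cfg, f"{sp}_posterior")
        lifted_cons = lift_peaks(cons, chains, min_match=cfg.min_match)
        lifted_all = lift_peaks(both, chains, min_match=cfg.min_match)
        sio.write_intervals(
            _out(cfg, "lift", f"{sp}_consensus_lifted.bed"), lifted_cons, "scored-peak"
        )
        sio.write_intervals(
            _out(cfg, "lift", f"{sp}_all_lifted.bed"), lifted_all, "scored-peak"
        )
        logger.info("lift[%s]: %d/%d consensus peaks lifted", sp, len(lifted_cons), len(cons))


def stage_triangulate(cfg: PipelineConfig) -> None:
    chimp_lift = sio.read_intervals(_out(cfg, "lift", "chimpanzee_consensus_lifted.bed"), "scored-peak")
    mac_lift = sio.read_intervals(_out(cfg, "lift", "macaque_consensus_lifted.bed"), "scored-peak")
    chimp_all = sio.read_intervals(_out(cfg, "lift", "chimpanzee_all_lifted.bed"), "scored-peak")
    mac_all = sio.read_intervals(_out(cfg, "lift", "macaque_all_lifted.bed"), "scored-peak")
    human_a = _load_peaks(cfg, "human_poisson")
    human_b = _load_peaks(cfg, "human_posterior")
    human_cons = _load_peaks(cfg, "human_consensus")
    blacklist = sio.read_intervals(_out(cfg, "annot", "blacklist.bed"))
    chains = {
        ("human", sp): _load_chains(cfg, "human", sp) for sp in NONREF
    } | {(sp, "human"): _load_chains(cfg, sp, "human") for sp in NONREF}

    shared = shared_nonhuman(chimp_lift, mac_lift)
    hypo = call_hypo(shared, human_a, human_b)
    hyper = call_hyper(human_cons, chimp_all, mac_all, chains, blacklist, cfg.min_match)
    two_species = call_hypo(chimp_lift, human_a, human_b)
    gain = triangulation_gain(two_species, hypo)

    sio.write_intervals(_out(cfg, "sdmr", "hypo.bed"), [s.interval for s in hypo])
    sio.write_intervals(_out(cfg, "sdmr", "hyper.bed"), [s.interval for s in hyper])
    sio.write_intervals(
        _out(cfg, "sdmr", "hypo_two_species.bed"), [s.interval for s in two_species]
    )
    fragments = {sp: _load_fragments(cfg, sp) for sp in SPECIES}
    bench = benchmark_sdmr_signal(hypo + hyper, fragments, chains, cfg.min_match)
    _write_json(_out(cfg, "sdmr", "benchmark.json"), bench)
    _write_json(
        _out(cfg, "sdmr", "gain.json"),
        {
            "triangulated_hypo": len(hypo),
            "two_species_hypo": len(two_species),
            "hyper": len(hyper),
            "triangulation_gain": gain,
        },
    )
    logger.info(
        "triangulate: %d hypo, %d hyper, two-species %d (gain %s)",
        len(hypo), len(hyper), len(two_species), gain,
    )


def _load_sdmrs(cfg: PipelineConfig, cls: str) -> list[GenomicInterval]:
    return sio.read_intervals(_out(cfg, "sdmr", f"{cls}.bed"))


def stage_enrich(cfg: PipelineConfig) -> None:
    sizes = _read_json(_out(cfg, "chrom_sizes.json"))
    human_sizes = {c: int(n) for c, n in sizes["human"].items()}
    islands = sio.read_intervals(_out(cfg, "annot", "islands.bed"))
    shores = make_shores(islands, human_sizes, flank=cfg.shore_flank)
    island_fs = FeatureSet("islands", islands)
    report: dict = {"island_bp": island_fs.total_bp, "shore_bp": shores.total_bp}
    backgrounds = {
        "hypo": [
            p.interval
            for p in sio.read_intervals(_out(cfg, "lift", "chimpanzee_consensus_lifted.bed"), "scored-peak")
        ],
        "hyper": [p.interval for p in _load_peaks(cfg, "human_consensus")],
    }
    combined_counts = {"island": 0, "shore": 0, "n": 0}
    for cls in ("hypo", "hyper"):
        regions = _load_sdmrs(cfg, cls)
        k_isl = count_overlaps(regions, island_fs, cfg.island_min_fraction)
        k_sho = count_overlaps(regions, shores, cfg.island_min_fraction)
        bg = backgrounds[cls]
        bg_isl = count_overlaps(bg, island_fs, cfg.island_min_fraction)
        bg_sho = count_overlaps(bg, shores, cfg.island_min_fraction)
        entry = {
            "n_sdmr": len(regions),
            "islands": k_isl,
            "shores": k_sho,
            "island_density_per_mb": density_per_mb(k_isl, island_fs.total_bp),
            "shore_density_per_mb": density_per_mb(k_sho, shores.total_bp),
        }
        if (k_isl + k_sho) > 0 and (bg_isl + bg_sho) > 0:
            chi = chi2_enrichment(k_sho, k_sho + k_isl, bg_sho, bg_sho + bg_isl)
            entry["shore_vs_island_chi2"] = {
                "ratio": chi.ratio, "p": chi.p_value, "method": chi.method,
            }
        report[cls] = entry
        combined_counts["island"] += k_isl
        combined_counts["shore"] += k_sho
        combined_counts["n"] += len(regions)
    if combined_counts["n"]:
        report["combined_island_density_per_mb"] = density_per_mb(
            combined_counts["island"], island_fs.total_bp
        )
        report["combined_shore_density_per_mb"] = density_per_mb(
            combined_counts["shore"], shores.total_bp
        )
    # repeat-subfamily overlaps for hyper s-DMRs + shuffle control vs islands
    repeats = sio.read_intervals(_out(cfg, "annot", "repeats.bed")) if (
        _out(cfg, "annot", "repeats.bed").exists()
    ) else []
    hyper_regions = _load_sdmrs(cfg, "hyper")
    if repeats and hyper_regions:
        by_subfam: dict[str, list] = {}
        for r in repeats:
            by_subfam.setdefault(r.name, []).append(r)
        report["hyper_repeat_overlaps"] = {
            sub: count_overlaps(hyper_regions, ivs, 0.0) for sub, ivs in by_subfam.items()
        }
    hypo_regions = _load_sdmrs(cfg, "hypo")
    if hypo_regions:
        blacklist = sio.read_intervals(_out(cfg, "annot", "blacklist.bed"))
        ctrl = shuffle_control(
            hypo_regions, human_sizes, island_fs, n_controls=50,
            seed=cfg.seed + 7, blacklist=blacklist,
        )
        report["hypo_island_shuffle"] = {
            "observed": ctrl.observed,
            "control_mean": ctrl.expected,
            "ratio": ctrl.ratio,
            "empirical_p": ctrl.empirical_p,
        }
    _write_json(_out(cfg, "enrich", "enrichment.json"), report)
    logger.info("enrich: %s", {k: v for k, v in report.items() if "density" in str(k)})


def _bundled_motif_path() -> Path:
    return Path(resources.files("sdmrkit").joinpath("data", "demo_motifs.txt"))


def _sdmr_triplets(
    cfg: PipelineConfig, regions: list[GenomicInterval], genomes: dict, chains: dict
) -> list[RegionTriplet]:
    triplets = []
    for iv in regions:
        if len(iv) > 5000:
            continue
        seqs = {"human": genomes["human"][iv.chrom][iv.start : iv.end]}
        ok = True
        for sp in NONREF:
            m = liftover(iv, chains[("human", sp)], min_match=cfg.min_match)
            if m.status != "mapped":
                ok = False
                break
            seqs[sp] = genomes[sp][m.target.chrom][m.target.start : m.target.end]
        if ok and all(seqs.values()):
            triplets.append(
                RegionTriplet(iv.name, seqs["human"], seqs["chimpanzee"], seqs["macaque"])
            )
    return triplets


def stage_motifs(cfg: PipelineConfig) -> None:
    genome_dir = _out(cfg, "genomes")
    if not (genome_dir / "human.fa").exists():
        _write_json(_out(cfg, "motifs", "divergence.json"), {"status": "skipped: no genome sequence"})
        return
    genomes = {sp: sio.read_fasta(genome_dir / f"{sp}.fa") for sp in SPECIES}
    chains = {("human", sp): _load_chains(cfg, "human", sp) for sp in NONREF}
    motif_path = Path(cfg.motif_file) if cfg.motif_file else _bundled_motif_path()
    matrices = sio.read_weight_matrices(motif_path)
    model = AffinityModel()
    hypo = _load_sdmrs(cfg, "hypo")
    islands = sio.read_intervals(_out(cfg, "annot", "islands.bed"))
    in_islands = [iv for iv, hit in zip(hypo, overlaps_any(hypo, islands)) if hit]
    regions = (in_islands or hypo)[: cfg.motif_max_regions]
    triplets = _sdmr_triplets(cfg, regions, genomes, chains)
    if not triplets:
        _write_json(_out(cfg, "motifs", "divergence.json"), {"status": "skipped: no mappable regions"})
        return
    # background: island sequences from the reference genome
    background = [
        genomes["human"][iv.chrom][iv.start : iv.end]
        for iv in islands
        if len(iv) >= 200
    ]
    per_species_seqs = {
        "human": [t.seq_human for t in triplets],
        "chimpanzee": [t.seq_chimp for t in triplets],
        "macaque": [t.seq_macaque for t in triplets],
    }
    raw_p: dict[str, dict[str, float]] = {}
    for wm in matrices:
        raw_p[wm.id] = {
            sp: region_set_pvalue(
                seqs, wm, background, model, b_draws=cfg.motif_b_draws,
                rng=np.random.default_rng(
                    [cfg.seed, zlib.crc32(wm.id.encode()), i]
                ),
            )
            for i, (sp, seqs) in enumerate(per_species_seqs.items())
        }
    adjusted: dict[str, dict[str, float]] = {m: {} for m in raw_p}
    for sp in SPECIES:
        adj = bh_adjust([raw_p[m][sp] for m in raw_p])
        for m, v in zip(raw_p, adj):
            adjusted[m][sp] = float(v)
    records = divergence_map(adjusted, threshold=cfg.divergence_threshold)
    pd.DataFrame([asdict(r) for r in records]).to_csv(
        _out(cfg, "motifs", "divergence.tsv"), sep="\t", index=False
    )
    flagged = [r.motif_id for r in records if r.consistent]
    # orthologous sequence identity of the analysed regions
    ident_hc = [orthologous_identity(t.seq_human, t.seq_chimp) for t in triplets
                if len(t.seq_human) == len(t.seq_chimp)]
    ident_hm = [orthologous_identity(t.seq_human, t.seq_macaque) for t in triplets
                if len(t.seq_human) == len(t.seq_macaque)]
    _write_json(
        _out(cfg, "motifs", "divergence.json"),
        {
            "status": "ok",
            "n_regions": len(triplets),
            "n_motifs": len(matrices),
            "flagged": flagged,
            "mean_identity_HC": float(np.mean(ident_hc)) if ident_hc else None,
            "mean_identity_HM": float(np.mean(ident_hm)) if ident_hm else None,
        },
    )
    logger.info("motifs: %d regions x %d motifs, flagged=%s", len(triplets), len(matrices), flagged)


def stage_rank(cfg: PipelineConfig) -> None:
    gene_path = _out(cfg, "annot", "genes.tsv")
    if not gene_path.exists():
        return
    genes = _genes_from_tsv(gene_path)
    islands = sio.read_intervals(_out(cfg, "annot", "islands.bed"))
    chains = {("human", sp): _load_chains(cfg, "human", sp) for sp in NONREF}
    peaks = {sp: _load_peaks(cfg, f"{sp}_poisson") for sp in SPECIES}
    for cls in ("hypo", "hyper"):
        sdmrs = _load_sdmrs(cfg, cls)
        selected = promoter_sdmr_transcripts(sdmrs, genes, islands)
        records = []
        for gene in selected:
            scores = {}
            for sp in SPECIES:
                if sp == "human":
                    exons = list(gene.exons)
                else:
                    exons = []
                    for e in gene.exons:
                        m = liftover(e, chains[("human", sp)], min_match=cfg.min_match)
                        if m.status == "mapped":
                            exons.append(m.target)
                        else:
                            logger.warning(
                                "rank: exon %s:%d-%d unmappable to %s; scored 0",
                                e.chrom, e.start, e.end, sp,
                            )
                scores[sp] = exon_score(exons, peaks[sp])
            records.append(
                make_record(gene.transcript_id, scores["human"],
                            scores["chimpanzee"], scores["macaque"])
            )
        table = rank_records(records, cls)
        table.to_csv(_out(cfg, "rank", f"{cls}_ranked.tsv"), sep="\t", index=False)
        logger.info("rank[%s]: %d promoter-s-DMR transcripts", cls, len(table))


def evaluate_recovery(cfg: PipelineConfig) -> dict:
    """Confusion summary of called s-DMRs against the planted truth."""
    truth = pd.read_csv(_out(cfg, "annot", "truth.tsv"), sep="\t")
    planted = {
        cls: [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in truth[truth["class"] == cls].itertuples()
        ]
        for cls in truth["class"].unique()
    }
    out = {}
    for cls, truth_cls in (("hypo", "human_hypo"), ("hyper", "human_hyper")):
        called = _load_sdmrs(cfg, cls)
        tp_planted = (
            int(overlaps_any(planted.get(truth_cls, []), called).sum())
            if planted.get(truth_cls)
            else 0
        )
        n_planted = len(planted.get(truth_cls, []))
        correct_calls = (
            int(overlaps_any(called, planted.get(truth_cls, [])).sum()) if called else 0
        )
        confounders = planted.get("chimp_only", []) + planted.get("shared_methylated", [])
        cross = int(overlaps_any(called, confounders).sum()) if called else 0
        out[cls] = {
            "planted": n_planted,
            "called": len(called),
            "recovered": tp_planted,
            "sensitivity": tp_planted / n_planted if n_planted else None,
            "precision": correct_calls / len(called) if called else None,
            "cross_class_calls": cross,
        }
    return out


def make_report(cfg: PipelineConfig) -> dict:
    """Assemble the run summary from persisted stage outputs."""
    required = [
        _out(cfg, "fragments", "totals.json"),
        _out(cfg, "sdmr", "gain.json"),
    ]
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")
    report: dict = {"fragments_retained": _read_json(_out(cfg, "fragments", "totals.json"))}
    peak_counts = {}
    for sp in SPECIES:
        for caller in ("poisson", "posterior", "consensus"):
            path = _out(cfg, "peaks", f"{sp}_{caller}.bed")
            if path.exists():
                peak_counts[f"{sp}_{caller}"] = len(sio.read_intervals(path, "scored-peak"))
    report["peaks"] = peak_counts
    report["sdmr"] = _read_json(_out(cfg, "sdmr", "gain.json"))
    enrich_path = _out(cfg, "enrich", "enrichment.json")
    if enrich_path.exists():
        report["enrichment"] = _read_json(enrich_path)
    motif_path = _out(cfg, "motifs", "divergence.json")
    if motif_path.exists():
        report["motifs"] = _read_json(motif_path)
    if cfg.mode == "synthetic" and _out(cfg, "annot", "truth.tsv").exists():
        report["recovery"] = evaluate_recovery(cfg)
    lines = [f"{k}: {json.dumps(v, sort_keys=True, default=float)}" for k, v in report.items()]
    _out(cfg, "report", "report.txt").write_text("\n".join(lines) + "\n")
    _write_json(_out(cfg, "report", "report.json"), report)
    return report


STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "peaks": stage_peaks,
    "lift": stage_lift,
    "triangulate": stage_triangulate,
    "enrich": stage_enrich,
    "motifs": stage_motifs,
    "rank": stage_rank,
}


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order and return the run report."""
    t0 = time.time()
    resolved = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    _out(cfg, "config_resolved.yaml").write_text(resolved)
    cfg_hash = hashlib.sha256(resolved.encode()).hexdigest()[:16]
    for name, fn in STAGES.items():
        try:
            fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    report = make_report(cfg)
    return RunReport(counts=report, config_hash=cfg_hash, wallclock_s=time.time() - t0)
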