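"""Readers and writers for the text formats the pipeline exchanges.

Intervals travel as BED3/BED6, peaks as BED6 plus summit/caller columns,
pairwise alignments as UCSC chain files, sequences as FASTA, motifs as
count matrices, and coverage as bedGraph. Everything round-trips losslessly
for valid inputs.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Chain, ChainSet, GenomicInterval, ScoredPeak, WeightMatrix

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_chain",
    "write_chain",
    "read_fasta",
    "write_fasta",
    "read_weight_matrix",
    "read_weight_matrices",
    "write_bedgraph",
]

_VALID_SEQ_CHARS = set("ACGTNacgtn")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_bed_line(line: str, lineno: int, dialect: str):
    fields = line.rstrip("\n").split("\t")
    min_cols = {"bed3": 3, "bed6": 3, "scored-peak": 5}[dialect]
    if len(fields) < min_cols:
        raise ParseError(f"line {lineno}: expected >= {min_cols} columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate: {exc}") from None
    if start >= end or start < 0:
        raise ParseError(f"line {lineno}: invalid span {start}-{end} (need 0 <= start < end)")
    name = fields[3] if len(fields) > 3 and fields[3] else "."
    strand = fields[5] if len(fields) > 5 and fields[5] else "."
    try:
        interval = GenomicInterval(chrom, start, end, name=name, strand=strand)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    if dialect == "scored-peak":
        try:
            score = float(fields[4])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric score {fields[4]!r}") from None
        summit = int(fields[6]) if len(fields) > 6 else (end - start) // 2
        caller = fields[7] if len(fields) > 7 else "poisson"
        try:
            return ScoredPeak(interval, score=score, summit=summit, caller=caller)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return interval


def read_intervals(path, dialect: str = "bed6"):
    """Read a BED-like file into GenomicInterval or ScoredPeak records.

    ``dialect`` is one of ``bed3``, ``bed6`` (both yield GenomicInterval;
    bed6 keeps name/strand) or ``scored-peak`` (BED6 + summit + caller
    columns, yielding ScoredPeak). Input order is preserved; malformed
    lines raise :class:`ParseError` naming the line number.
    """
    if dialect not in ("bed3", "bed6", "scored-peak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed_line(line, lineno, dialect))
    return out


def write_intervals(path, records: Iterable, dialect: str = "bed6") -> None:
    """Write intervals/peaks as tab-separated BED; inverse of read_intervals.

    Peak scores are written to one decimal place (transformed-p convention
    of the exported peak tracks).
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ScoredPeak):
                iv = rec.interval
                if dialect == "scored-peak":
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                        f"{rec.score:.1f}\t{iv.strand}\t{rec.summit}\t{rec.caller}\n"
                    )
                else:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                        f"{rec.score:.1f}\t{iv.strand}\n"
                    )
            else:
                if dialect == "bed3":
                    fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
                else:
                    fh.write(
                        f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t0\t{rec.strand}\n"
                    )


def read_chain(path) -> ChainSet:
    """Parse a UCSC chain file; block-sum invariants are checked per chain."""
    chains: list[Chain] = []
    current: Chain | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                parts = line.split()
                if len(parts) not in (12, 13):
                    raise ParseError(f"line {lineno}: chain header needs 12-13 fields")
                current = Chain(
                    score=int(parts[1]),
                    source_chrom=parts[2],
                    source_size=int(parts[3]),
                    source_strand=parts[4],
                    source_start=int(parts[5]),
                    source_end=int(parts[6]),
                    target_chrom=parts[7],
                    target_size=int(parts[8]),
                    target_strand=parts[9],
                    target_start=int(parts[10]),
                    target_end=int(parts[11]),
                    chain_id=int(parts[12]) if len(parts) == 13 else len(chains) + 1,
                )
                chains.append(current)
            else:
                if current is None:
                    raise ParseError(f"line {lineno}: block line before any chain header")
                parts = line.split()
                try:
                    nums = [int(p) for p in parts]
                except ValueError:
                    raise ParseError(f"line {lineno}: non-integer block field") from None
                if len(nums) == 1:
                    current.blocks.append((nums[0], 0, 0))
                    current = None  # terminal block closes the chain
                elif len(nums) == 3:
                    current.blocks.append((nums[0], nums[1], nums[2]))
                else:
                    raise ParseError(f"line {lineno}: block line needs 1 or 3 fields")
    for chain in chains:
        chain.validate()
    return ChainSet(chains)


def write_chain(path, chainset: ChainSet) -> None:
    with open(path, "w") as fh:
        for c in chainset:
            fh.write(
                f"chain {c.score} {c.source_chrom} {c.source_size} {c.source_strand} "
                f"{c.source_start} {c.source_end} {c.target_chrom} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
            )
            for i, (size, dsrc, dtgt) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n\n")
                else:
                    fh.write(f"{size}\t{dsrc}\t{dtgt}\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} dict.

    Case is preserved; duplicate names and characters outside
    {A,C,G,T,N} (either case) are errors.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate sequence name {record.id!r}")
        seq = str(record.seq)
        bad = set(seq) - _VALID_SEQ_CHARS
        if bad:
            raise ValueError(
                f"sequence {record.id!r} contains illegal characters {sorted(bad)}"
            )
        out[record.id] = seq
    return out


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _parse_matrix_block(block_lines: Sequence[tuple[int, str]], motif_id: str, pseudocount: float) -> WeightMatrix:
    rows = []
    for lineno, line in block_lines:
        parts = line.split()
        if len(parts) == 5:  # leading position index column
            parts = parts[1:]
        if len(parts) != 4:
            raise ParseError(f"line {lineno}: expected 4 count columns, got {len(parts)}")
        try:
            row = [float(p) for p in parts]
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric count") from None
        rows.append(row)
    if not rows:
        raise ParseError(f"matrix {motif_id!r} has zero width")
    return WeightMatrix(motif_id, rows, pseudocount=pseudocount)


def read_weight_matrices(path, pseudocount: float = 1.0) -> list[WeightMatrix]:
    """Read one or more count matrices (TRANSFAC-like).

    Format: a ``>ID`` header line starts each motif, followed by one row of
    4 base counts (A C G T; an optional leading position index column is
    tolerated) per motif position.
    """
    matrices = []
    motif_id = None
    block: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if motif_id is not None:
                    matrices.append(_parse_matrix_block(block, motif_id, pseudocount))
                motif_id = line[1:].split()[0]
                block = []
            else:
                if motif_id is None:
                    raise ParseError(f"line {lineno}: count row before any >ID header")
                block.append((lineno, line))
    if motif_id is not None:
        matrices.append(_parse_matrix_block(block, motif_id, pseudocount))
    return matrices


def read_weight_matrix(path, pseudocount: float = 1.0) -> WeightMatrix:
    """Read a single count matrix; errors if the file holds more than one."""
    matrices = read_weight_matrices(path, pseudocount=pseudocount)
    if len(matrices) != 1:
        raise ValueError(f"expected exactly one matrix in {path}, found {len(matrices)}")
    return matrices[0]


def write_bedgraph(path, chrom_values: dict[str, "tuple"], bin_width: int) -> None:
    """Write binned per-chromosome values as bedGraph (zero bins skipped)."""
    with open(path, "w") as fh:
        for chrom, values in chrom_values.items():
            for i, v in enumerate(values):
                if v:
                    fh.write(f"{chrom}\t{i * bin_width}\t{(i + 1) * bin_width}\t{v:g}\n")
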