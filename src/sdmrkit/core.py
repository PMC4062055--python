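"""Core coordinate and matrix types shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED convention). Any 1-based
coordinate only ever appears in rendered reports, never in data structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "ScoredPeak",
    "Chain",
    "ChainSet",
    "WeightMatrix",
    "BASES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded; the default —
    MeDIP enrichment carries no strand information).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ScoredPeak:
    """An enrichment peak with a transformed p-value score.

    ``score`` defaults to the MACS convention -10*log10(p). ``summit`` is a
    bp offset from ``interval.start``. ``caller`` identifies which of the
    two independent callers produced the peak.
    """

    interval: GenomicInterval
    score: float
    summit: int
    caller: str = "poisson"

    def __post_init__(self) -> None:
        if not math.isfinite(self.score) or self.score < 0:
            raise ValueError(f"peak score must be finite and >= 0, got {self.score}")
        if not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length "
                f"{len(self.interval)}"
            )
        if self.caller not in ("poisson", "posterior"):
            raise ValueError(f"unknown caller {self.caller!r}")


@dataclass
class Chain:
    """One gapped alignment chain between a source and a target assembly.

    Blocks are ``(size, dsource, dtarget)`` triples: ``size`` aligned bases
    followed by a ``dsource``-bp gap on the source side and a ``dtarget``-bp
    gap on the target side (both zero on the final block). Target
    coordinates are stored exactly as in the chain file: when
    ``target_strand == '-'`` they count along the reverse strand and are
    converted to forward coordinates during mapping.
    """

    score: int
    source_chrom: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    chain_id: int = 0

    def validate(self) -> None:
        sizes = sum(b[0] for b in self.blocks)
        dsrc = sum(b[1] for b in self.blocks)
        dtgt = sum(b[2] for b in self.blocks)
        if sizes + dsrc != self.source_end - self.source_start:
            raise ValueError(
                f"chain {self.chain_id}: block sizes + source gaps "
                f"({sizes}+{dsrc}) != declared source span "
                f"({self.source_end - self.source_start})"
            )
        if sizes + dtgt != self.target_end - self.target_start:
            raise ValueError(
                f"chain {self.chain_id}: block sizes + target gaps "
                f"({sizes}+{dtgt}) != declared target span "
                f"({self.target_end - self.target_start})"
            )
        if self.blocks and (self.blocks[-1][1] or self.blocks[-1][2]):
            raise ValueError(f"chain {self.chain_id}: final block carries gaps")

    def segments(self) -> np.ndarray:
        """Ungapped segments as an array of (src_start, tgt_start, length).

        Both coordinates are in chain-file orientation (target coordinates
        still reverse-strand when ``target_strand == '-'``).
        """
        segs = np.empty((len(self.blocks), 3), dtype=np.int64)
        s, t = self.source_start, self.target_start
        for i, (size, dsrc, dtgt) in enumerate(self.blocks):
            segs[i] = (s, t, size)
            s += size + dsrc
            t += size + dtgt
        return segs


@dataclass
class ChainSet:
    """All chains of one pairwise liftover file (one source→target build)."""

    chains: list[Chain]

    def __iter__(self):
        return iter(self.chains)

    def __len__(self) -> int:
        return len(self.chains)

    def by_source_chrom(self, chrom: str) -> list[Chain]:
        return [c for c in self.chains if c.source_chrom == chrom]


class WeightMatrix:
    """A position count/weight matrix over {A, C, G, T}.

    Frequencies are ``(count + pseudocount) / (row_sum + 4 * pseudocount)``
    so every base has non-zero probability at every position.
    """

    def __init__(self, motif_id: str, counts, pseudocount: float = 1.0):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a (W, 4) array")
        if counts.shape[0] < 1:
            raise ValueError("zero-width matrix")
        if np.any(counts < 0):
            raise ValueError(f"negative count in matrix {motif_id!r}")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.id = motif_id
        self.counts = counts
        self.pseudocount = float(pseudocount)
        row_sums = counts.sum(axis=1, keepdims=True)
        self.frequencies = (counts + pseudocount) / (row_sums + 4.0 * pseudocount)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=1))

    def __repr__(self) -> str:
        return f"WeightMatrix(id={self.id!r}, width={self.width})"


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an upper-case DNA string as int8 (A=0 C=1 G=2 T=3, N/other=-1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    safe = np.where(codes < 0, 4, codes).astype(np.intp)
    return lut[safe].tobytes().decode("ascii")
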