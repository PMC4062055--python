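import numpy as np
import pytest

from sdmrkit.core import GenomicInterval
from sdmrkit.synthetic import TrioConfig, generate_trio, simulate_trio_medip


def small_trio_config(seed: int = 7) -> TrioConfig:
    """Reduced-scale trio for unit tests (fast, still full-featured)."""
    return TrioConfig(
        chrom_count=2,
        chrom_length=200_000,
        island_count=12,
        gene_count=8,
        linked_genes=2,
        repeat_count=15,
        blacklist_count=2,
        planted_counts={
            "human_hypo": 6,
            "human_hyper": 6,
            "chimp_only": 4,
            "shared_methylated": 4,
            "unmethylated_background": 4,
        },
        motif_edit_count=2,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_trio():
    return generate_trio(small_trio_config())


@pytest.fixture(scope="session")
def small_trio_fragments(small_trio):
    return simulate_trio_medip(small_trio)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=300):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return out


def brute_force_liftover(interval, chainset):
    """Per-base mapping oracle: walk every base through every chain."""
    per_chain = {}
    for chain in chainset:
        if chain.source_chrom != interval.chrom:
            continue
        mapped = []
        s, t = chain.source_start, chain.target_start
        for size, dsrc, dtgt in chain.blocks:
            if s < interval.end and interval.start < s + size:
                for k in range(size):  # per-base walk inside the block
                    p = s + k
                    if interval.start <= p < interval.end:
                        q = t + k
                        if chain.target_strand == "-":
                            q = chain.target_size - 1 - q
                        mapped.append((q, chain.target_chrom))
            s += size + dsrc
            t += size + dtgt
        if mapped:
            per_chain[chain.chain_id] = mapped
    return per_chain
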