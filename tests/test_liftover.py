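"""Chain-based liftover against per-base brute-force mapping oracles."""

import numpy as np
import pytest

from sdmrkit.core import Chain, ChainSet, GenomicInterval
from sdmrkit.liftover import exclude_blacklist, liftover, reciprocal_filter

from conftest import brute_force_liftover


def _chain(blocks, src_len, tgt_len, tgt_strand="+", chrom="chr1", tgt_chrom="chrT", cid=1):
    c = Chain(
        score=1, source_chrom=chrom, source_size=src_len, source_strand="+",
        source_start=0, source_end=src_len, target_chrom=tgt_chrom,
        target_size=tgt_len, target_strand=tgt_strand, target_start=0,
        target_end=tgt_len, blocks=blocks, chain_id=cid,
    )
    c.validate()
    return c


class TestLiftover:
    def test_identity_chain(self):
        cs = ChainSet([_chain([(100, 0, 0)], 100, 100)])
        m = liftover(GenomicInterval("chr1", 10, 60), cs)
        assert m.status == "mapped"
        assert m.mapped_fraction == 1.0
        assert (m.target.start, m.target.end) == (10, 60)

    def test_fraction_at_threshold_is_mapped(self):
        # 100-bp interval with 30 bp falling in a source gap: fraction 0.70
        cs = ChainSet([_chain([(50, 30, 0), (120, 0, 0)], 200, 170)])
        m = liftover(GenomicInterval("chr1", 20, 120), cs, min_match=0.7)
        assert m.mapped_fraction == pytest.approx(0.70)
        assert m.status == "mapped"  # inclusive >= threshold

    def test_below_threshold_low_match(self):
        cs = ChainSet([_chain([(50, 60, 0), (90, 0, 0)], 200, 140)])
        m = liftover(GenomicInterval("chr1", 20, 120), cs, min_match=0.7)
        assert m.status == "low_match"

    def test_inside_source_gap_unmapped(self):
        cs = ChainSet([_chain([(50, 100, 0), (50, 0, 0)], 200, 100)])
        m = liftover(GenomicInterval("chr1", 60, 140), cs)
        assert m.status == "unmapped" and m.target is None

    def test_absent_chromosome_unmapped(self):
        cs = ChainSet([_chain([(100, 0, 0)], 100, 100)])
        assert liftover(GenomicInterval("chrZ", 0, 10), cs).status == "unmapped"

    def test_split_across_chains_fails(self):
        a = _chain([(50, 0, 0)], 50, 50, cid=1)
        b = Chain(
            score=1, source_chrom="chr1", source_size=200, source_strand="+",
            source_start=100, source_end=150, target_chrom="chrU", target_size=50,
            target_strand="+", target_start=0, target_end=50,
            blocks=[(50, 0, 0)], chain_id=2,
        )
        m = liftover(GenomicInterval("chr1", 40, 110), ChainSet([a, b]))
        assert m.status == "split" and m.target is None

    def test_negative_strand_matches_per_base_oracle(self):
        # 10-bp toy chain onto the reverse strand of a 30-bp target
        cs = ChainSet([_chain([(4, 2, 1), (4, 0, 0)], 10, 9, tgt_strand="-", tgt_chrom="chrT")])
        iv = GenomicInterval("chr1", 0, 10)
        m = liftover(iv, cs)
        oracle = brute_force_liftover(iv, cs)
        positions = [q for q, _ in oracle[1]]
        assert m.target.start == min(positions)
        assert m.target.end == max(positions) + 1
        assert m.mapped_fraction == len(positions) / len(iv)

    def test_random_chains_match_brute_force(self, rng):
        for trial in range(30):
            blocks = []
            src = tgt = 0
            for j in range(int(rng.integers(1, 6))):
                size = int(rng.integers(5, 60))
                dsrc = int(rng.integers(0, 30))
                dtgt = int(rng.integers(0, 30))
                blocks.append((size, dsrc, dtgt))
                src += size + dsrc
                tgt += size + dtgt
            last = blocks.pop()
            blocks.append((last[0], 0, 0))
            src -= last[1]
            tgt -= last[2]
            strand = "+" if rng.random() < 0.5 else "-"
            cs = ChainSet([_chain(blocks, src, tgt, tgt_strand=strand)])
            for _ in range(20):
                s = int(rng.integers(0, src - 1))
                e = int(rng.integers(s + 1, src + 1))
                iv = GenomicInterval("chr1", s, e)
                m = liftover(iv, cs, min_match=0.0)
                oracle = brute_force_liftover(iv, cs)
                if not oracle:
                    assert m.status == "unmapped"
                    continue
                positions = [q for q, _ in oracle[1]]
                assert m.mapped_fraction == pytest.approx(len(positions) / len(iv))
                assert m.target.start == min(positions)
                assert m.target.end == max(positions) + 1

    def test_mapped_fraction_monotone_under_gap_insertion(self):
        """Growing a source gap never increases the mapped fraction."""
        iv = GenomicInterval("chr1", 10, 110)
        prev = 1.0
        for gap in range(0, 80, 10):
            cs = ChainSet([_chain([(50, gap, 0), (150 - gap, 0, 0)], 200, 200 - gap)])
            frac = liftover(iv, cs, min_match=0.0).mapped_fraction
            assert frac <= prev + 1e-12
            prev = frac


class TestTrioRoundTrip:
    def test_round_trip_identity_on_unedited_blocks(self, small_trio, rng):
        """H->C->H returns intervals in unedited blocks exactly."""
        trio = small_trio
        fwd = trio.chains[("human", "chimpanzee")]
        rev = trio.chains[("chimpanzee", "human")]
        checked = 0
        sizes = trio.config.chrom_sizes
        indel_pos = {
            c: trio.edit_log["chimpanzee"][c].query("kind != 'sub'") for c in sizes
        }
        attempts = 0
        while checked < 1000 and attempts < 20000:
            attempts += 1
            chrom = list(sizes)[int(rng.integers(len(sizes)))]
            start = int(rng.integers(0, sizes[chrom] - 400))
            iv = GenomicInterval(chrom, start, start + int(rng.integers(50, 400)))
            log = indel_pos[chrom]
            near = log[
                (log["pos"] + log["length"] >= iv.start - 1) & (log["pos"] <= iv.end + 1)
            ]
            if len(near):
                continue
            m = liftover(iv, fwd)
            assert m.status == "mapped" and m.mapped_fraction == 1.0
            back = liftover(m.target, rev)
            assert back.status == "mapped"
            assert (back.target.chrom, back.target.start, back.target.end) == (
                iv.chrom, iv.start, iv.end,
            )
            checked += 1
        assert checked == 1000


class TestReciprocalFilter:
    def test_identity_chains_retain_all(self):
        cs = ChainSet([_chain([(1000, 0, 0)], 1000, 1000, tgt_chrom="chr1")])
        ivs = [GenomicInterval("chr1", 10, 50), GenomicInterval("chr1", 600, 900)]
        assert reciprocal_filter(ivs, cs, cs) == ivs

    def test_empty_input(self):
        cs = ChainSet([_chain([(10, 0, 0)], 10, 10)])
        assert reciprocal_filter([], cs, cs) == []

    def test_interval_lost_on_return_path_dropped(self, small_trio):
        """A region deleted on the chimpanzee branch cannot lift forward."""
        trio = small_trio
        log = trio.edit_log["chimpanzee"]["chr1"]
        dels = log[(log["kind"] == "del") & (log["length"] >= 2)]
        assert len(dels)
        r = dels.iloc[0]
        iv = GenomicInterval("chr1", int(r.pos), int(r.pos + r.length))
        fwd = trio.chains[("human", "chimpanzee")]
        rev = trio.chains[("chimpanzee", "human")]
        assert reciprocal_filter([iv], fwd, rev) == []

    def test_strict_mode_requires_exact_coordinates(self):
        # forward loses the interval's trailing 10 bp => back-lift lands on
        # a truncated span: overlap mode keeps it, strict mode drops it
        fwd = ChainSet([_chain([(50, 10, 0), (140, 0, 0)], 200, 190)])
        rev = ChainSet(
            [_chain([(50, 0, 10), (140, 0, 0)], 190, 200, chrom="chrT", tgt_chrom="chr1")]
        )
        iv = GenomicInterval("chr1", 40, 60)
        assert reciprocal_filter([iv], fwd, rev, min_match=0.5) == [iv]
        assert reciprocal_filter([iv], fwd, rev, min_match=0.5, strict=True) == []


class TestBlacklist:
    def test_empty_blacklist_identity(self):
        ivs = [GenomicInterval("chr1", 0, 10)]
        assert exclude_blacklist(ivs, []) == ivs

    def test_abutting_interval_retained(self):
        ivs = [GenomicInterval("chr1", 0, 100)]
        blk = [GenomicInterval("chr1", 100, 200)]
        assert exclude_blacklist(ivs, blk) == ivs

    def test_matches_brute_force(self, rng):
        from conftest import random_intervals

        ivs = random_intervals(rng, 80)
        blk = random_intervals(rng, 40)
        got = exclude_blacklist(ivs, blk)
        expected = [a for a in ivs if not any(a.overlaps(b) for b in blk)]
        assert got == expected
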