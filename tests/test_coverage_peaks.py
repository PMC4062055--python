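"""Fragment filtering, normalization, coverage tracks and both callers."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from sdmrkit.coverage import (
    CoverageTrack,
    FragmentSet,
    filter_fragments,
    normalize_to_reference,
    rpm_track,
)
from sdmrkit.core import GenomicInterval, ScoredPeak
from sdmrkit.peaks import (
    call_peaks_poisson,
    call_peaks_posterior,
    consensus,
)


def _frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "quality", "proper_pair"])


class TestFilter:
    def test_duplicates_collapse_to_one(self):
        rows = [("chr1", 0, 100, 60, True)] * 3
        assert filter_fragments(_frame(rows)).total_retained == 1

    def test_all_low_quality_empty(self):
        rows = [("chr1", i, i + 50, 0, True) for i in range(5)]
        assert filter_fragments(_frame(rows)).total_retained == 0

    def test_mixed_set_matches_sequential_rule_oracle(self):
        # 10 fragments: 2 low-quality, 1 improper pair, 1 duplicate pair
        # (one of which is removed) -> 6 retained
        rows = [
            ("chr1", 0, 100, 60, True),
            ("chr1", 0, 100, 60, True),      # dup of row 0
            ("chr1", 200, 300, 5, True),     # low q
            ("chr1", 400, 500, 60, False),   # improper pair
            ("chr1", 600, 700, 60, True),
            ("chr1", 800, 900, 9, True),     # low q
            ("chr2", 0, 100, 60, True),
            ("chr2", 200, 300, 60, True),
            ("chr2", 400, 500, 60, True),
            ("chr2", 600, 700, 60, True),
        ]
        df = _frame(rows)
        got = filter_fragments(df)
        # brute-force oracle applying the three rules sequentially
        kept, seen = [], set()
        for r in rows:
            if not r[4] or r[3] < 10:
                continue
            key = r[:3]
            if key in seen:
                continue
            seen.add(key)
            kept.append(r)
        assert got.total_retained == len(kept) == 6
        assert [tuple(x) for x in got.frame[["chrom", "start", "end"]].itertuples(index=False)] == [
            k[:3] for k in kept
        ]

    def test_order_stable(self):
        rows = [("chr2", 500, 600, 60, True), ("chr1", 0, 100, 60, True)]
        out = filter_fragments(_frame(rows)).frame
        assert out["chrom"].tolist() == ["chr2", "chr1"]


class TestNormalize:
    def test_formula(self):
        assert normalize_to_reference(50, 1_000_000, 2_000_000) == 100.0

    def test_zero_reads(self):
        assert normalize_to_reference(0, 10, 20) == 0.0

    def test_identity_when_totals_equal(self):
        assert normalize_to_reference(37, 5_000, 5_000) == 37.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference(1, 0, 10)


class TestRpmTrack:
    def test_single_fragment(self):
        fs = FragmentSet("x", _frame([("chr1", 100, 200, 60, True)]))
        track = rpm_track(fs, 50, {"chr1": 1000})
        rpm = track.rpm()["chr1"]
        assert rpm[150 // 50] == 1e6
        assert rpm.sum() == 1e6

    def test_uniform_rpm(self):
        rows = [("chr1", i * 100, i * 100 + 50, 60, True) for i in range(100)]
        track = rpm_track(FragmentSet("x", _frame(rows)), 100, {"chr1": 10_000})
        assert np.all(track.rpm()["chr1"] == 1e4)

    def test_counts_sum_to_total(self, rng):
        rows = [
            ("chr1" if rng.random() < 0.5 else "chr2",
             int(s := rng.integers(0, 9_000)), int(s) + 120, 60, True)
            for _ in range(500)
        ]
        fs = FragmentSet("x", _frame(rows))
        track = rpm_track(fs, 37, {"chr1": 10_000, "chr2": 10_000})
        assert sum(v.sum() for v in track.counts.values()) == fs.total_retained


def _track_from_counts(counts, bin_width=50, chrom="chr1"):
    counts = np.asarray(counts, dtype=np.int64)
    return CoverageTrack(
        bin_width=bin_width,
        counts={chrom: counts},
        library_total=int(counts.sum()),
        chrom_sizes={chrom: len(counts) * bin_width},
    )


class TestPoissonCaller:
    def test_homogeneous_background_no_peaks(self):
        counts = np.full(2000, 5, dtype=np.int64)
        track = _track_from_counts(counts)
        assert call_peaks_poisson(track, fraglen=200) == []

    def test_tail_p_matches_direct_summation(self):
        """Upper-tail Poisson p equals term-by-term summation to 1e-12."""
        for lam in (0.5, 1.0, 7.3, 20.0):
            # recursive term evaluation avoids factorial overflow
            term = math.exp(-lam)
            terms = []
            for i in range(200):
                terms.append(term)
                term *= lam / (i + 1)
            for k in range(0, 51):
                direct = sum(terms[k:])
                assert poisson.sf(k - 1, lam) == pytest.approx(direct, abs=1e-12)

    def test_window_count_eight_scores_fortynine_nine(self):
        """A window of 8 at lambda=1 gives p~1.02e-5, score ~49.9."""
        counts = np.zeros(4000, dtype=np.int64)
        counts[2000] = 8
        counts[:1000] = 1  # background mass so lambda per 200-bp window ~ 1
        track = CoverageTrack(
            bin_width=50,
            counts={"chr1": counts},
            library_total=int(counts.sum()),
            chrom_sizes={"chr1": 4000 * 50},
        )
        # genome rate: total/genome_len * fraglen = lambda
        lam = track.library_total / track.genome_length * 200
        peaks = call_peaks_poisson(track, fraglen=200, p_threshold=1e-3)
        target = [p for p in peaks if p.interval.start <= 100_000 < p.interval.end]
        assert len(target) == 1
        expected_p = poisson.sf(7, lam)
        assert target[0].score == pytest.approx(-10 * math.log10(expected_p), abs=0.05)
        # with lambda close to 1 the textbook hand computation applies
        assert lam == pytest.approx(1.008, abs=1e-9)
        assert poisson.sf(7, 1.0) == pytest.approx(1.02e-5, rel=0.01)
        assert -10 * math.log10(poisson.sf(7, 1.0)) == pytest.approx(49.9, abs=0.05)

    def test_two_separated_peaks_not_merged(self):
        counts = np.ones(3000, dtype=np.int64)
        counts[1000:1004] = 30
        # separation of 3 x fraglen of background between significant windows
        counts[1016:1020] = 30
        track = _track_from_counts(counts)
        peaks = call_peaks_poisson(track, fraglen=200)
        assert len(peaks) == 2

    def test_adjacent_windows_merge_to_single_peak(self):
        counts = np.ones(3000, dtype=np.int64)
        counts[1000:1010] = 30
        track = _track_from_counts(counts)
        peaks = call_peaks_poisson(track, fraglen=200)
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 1000 * 50 < peaks[0].interval.end

    def test_empty_track(self):
        track = _track_from_counts(np.zeros(100, dtype=np.int64))
        assert call_peaks_poisson(track, fraglen=200) == []


class TestPosteriorCaller:
    def test_constant_counts_no_peaks(self):
        track = _track_from_counts(np.full(500, 4, dtype=np.int64))
        assert call_peaks_posterior(track) == []

    def test_requires_min_bins(self):
        track = _track_from_counts(np.arange(50, dtype=np.int64))
        with pytest.raises(ValueError, match="100 bins"):
            call_peaks_posterior(track)

    def test_bimodal_parameters_recovered_within_ten_percent(self, rng):
        """EM recovers a clearly bimodal mixture; cross-checked against a
        coarse grid-search over the likelihood surface."""
        from sdmrkit.peaks import _fit_poisson_mixture
        from scipy.special import gammaln

        n = 20_000
        enriched = rng.random(n) < 0.05
        counts = np.where(enriched, rng.poisson(20.0, n), rng.poisson(1.0, n))
        lam_bg, lam_en, pi_en, post = _fit_poisson_mixture(counts)
        assert lam_bg == pytest.approx(1.0, rel=0.10)
        assert lam_en == pytest.approx(20.0, rel=0.10)
        assert pi_en == pytest.approx(0.05, rel=0.15)

        def loglik(lb, le, pi):
            vals, cnts = np.unique(counts, return_counts=True)
            lf = gammaln(vals + 1.0)
            a = np.log1p(-pi) + vals * np.log(lb) - lb - lf
            b = np.log(pi) + vals * np.log(le) - le - lf
            return float(np.dot(cnts, np.logaddexp(a, b)))

        best_grid = max(
            (loglik(lb, le, pi), lb, le, pi)
            for lb in (0.8, 0.9, 1.0, 1.1, 1.2)
            for le in (16, 18, 20, 22, 24)
            for pi in (0.03, 0.05, 0.07)
        )
        assert loglik(lam_bg, lam_en, pi_en) >= best_grid[0] - 1e-6
        # bins with high counts are the ones called enriched
        assert post[counts >= 10].min() > 0.5

    def test_deterministic_given_input(self, rng):
        counts = np.where(rng.random(5000) < 0.04, rng.poisson(25.0, 5000), rng.poisson(2.0, 5000))
        track = _track_from_counts(counts)
        p1 = call_peaks_posterior(track)
        p2 = call_peaks_posterior(track)
        assert p1 == p2 and len(p1) > 0

    def test_fold_guard_suppresses_weak_separation(self, rng):
        counts = rng.poisson(10.0, size=5000)
        track = _track_from_counts(counts)
        # unimodal data: either no separation or guard kicks in
        assert call_peaks_posterior(track) == []


def _peak(chrom, start, end, score=10.0):
    return ScoredPeak(GenomicInterval(chrom, start, end, name=f"{chrom}:{start}"), score, 0)


class TestConsensus:
    def test_empty_b_empty_result(self):
        assert consensus([_peak("chr1", 0, 10)], []) == []

    def test_identity(self):
        a = [_peak("chr1", 0, 10), _peak("chr2", 5, 25)]
        assert consensus(a, a) == a

    def test_matches_brute_force(self, rng):
        from conftest import random_intervals

        a = [ScoredPeak(iv, 1.0, 0) for iv in random_intervals(rng, 60)]
        b = [ScoredPeak(iv, 1.0, 0) for iv in random_intervals(rng, 60)]
        got = consensus(a, b)
        expected = [
            pa for pa in a if any(pa.interval.overlaps(pb.interval) for pb in b)
        ]
        assert got == expected

    def test_idempotent(self, rng):
        from conftest import random_intervals

        a = [ScoredPeak(iv, 1.0, 0) for iv in random_intervals(rng, 40)]
        b = [ScoredPeak(iv, 1.0, 0) for iv in random_intervals(rng, 40)]
        once = consensus(a, b)
        assert consensus(once, b) == once
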