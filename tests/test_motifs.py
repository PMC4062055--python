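"""PWM occupancy model, aggregate p-values, divergence map, MDR screen."""

import math

import numpy as np
import pytest

from sdmrkit.core import WeightMatrix
from sdmrkit.motifs import (
    AffinityModel,
    RegionTriplet,
    bh_adjust,
    divergence_map,
    empirical_directional_p,
    expected_occupancy,
    mdr_screen,
    orthologous_identity,
    region_set_pvalue,
)

MODEL = AffinityModel()
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq))


def brute_occupancy(seq, wm, model=MODEL):
    """Exhaustive enumeration over every window on both strands."""
    W = wm.width
    freqs = wm.frequencies
    fmax = freqs.max(axis=1)
    total = 0.0
    ln_r0 = model.ln_r0(W)
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(seq) - W + 1):
            window = strand_seq[i : i + W]
            if "N" in window:
                continue
            E = sum(
                math.log(fmax[j] / freqs[j, "ACGT".index(window[j])]) for j in range(W)
            ) / model.lam
            x = math.exp(ln_r0 - E)
            total += x / (1 + x)
    return total


class TestOccupancy:
    def test_width_one_uniform_closed_form(self):
        wm = WeightMatrix("u", [[5, 5, 5, 5]])
        L = 40
        seq = "ACGT" * 10
        r0 = math.exp(MODEL.ln_r0(1))
        expected = 2 * L * r0 / (1 + r0)
        assert expected_occupancy(seq, wm, MODEL) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "counts,seq",
        [
            ([[9, 0, 1, 0], [0, 8, 0, 2]], "ACGTCA"),
            ([[1, 1, 8, 1]], "GGGAAT"),
            ([[4, 3, 2, 1], [1, 2, 3, 4], [10, 0, 0, 0]], "TTACGATC"),
            ([[2, 2, 2, 14], [6, 6, 1, 1], [0, 0, 12, 0], [3, 3, 3, 3]], "ACGTAGCTAN"),
        ],
    )
    def test_matches_exhaustive_window_enumeration(self, counts, seq):
        wm = WeightMatrix("m", counts)
        assert expected_occupancy(seq, wm, MODEL) == pytest.approx(
            brute_occupancy(seq, wm), abs=1e-9
        )

    def test_all_n_sequence_scores_zero(self):
        wm = WeightMatrix("m", [[9, 0, 1, 0], [0, 8, 0, 2]])
        assert expected_occupancy("NNNNNN", wm, MODEL) == 0.0

    def test_too_short_sequence_rejected(self):
        wm = WeightMatrix("m", [[1, 1, 1, 1]] * 5)
        with pytest.raises(ValueError, match="shorter"):
            expected_occupancy("ACG", wm, MODEL)

    def test_reverse_complement_invariance(self, rng):
        wm = WeightMatrix("m", rng.integers(0, 12, size=(6, 4)))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        assert expected_occupancy(seq, wm, MODEL) == pytest.approx(
            expected_occupancy(revcomp(seq), wm, MODEL), rel=1e-10
        )

    def test_mutation_toward_consensus_never_decreases_occupancy(self, rng):
        wm = WeightMatrix("m", [[12, 1, 1, 1], [1, 12, 1, 1], [1, 1, 12, 1]])
        consensus = wm.consensus()
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        for pos in range(10, 13):
            mutated = seq[:pos] + consensus[pos - 10] + seq[pos + 1 :]
            assert expected_occupancy(mutated, wm, MODEL) >= expected_occupancy(
                seq, wm, MODEL
            ) - 1e-12


class TestRegionSetPvalue:
    def test_background_identical_to_observed_gives_one(self):
        wm = WeightMatrix("m", [[9, 0, 1, 0], [0, 8, 0, 2]])
        regions = ["ACGTACGTAC"]
        p = region_set_pvalue(regions, wm, background=regions, b_draws=99, seed=0)
        assert p == 1.0

    def test_observed_exceeding_all_draws(self):
        wm = WeightMatrix("m", [[20, 0, 0, 0], [0, 0, 0, 20]])
        observed = ["ATATATATAT"]  # saturated with the consensus AT
        background = ["GCGCGCGCGCGCGCGCGCGC"]
        p = region_set_pvalue(observed, wm, background, b_draws=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_tiny_pool_matches_full_enumeration(self):
        """With a single possible background draw the p-value is exactly
        determined by one comparison."""
        wm = WeightMatrix("m", [[9, 0, 1, 0]])
        observed = ["AAAA"]
        background = ["CCCC"]  # only one length-4 draw exists
        p = region_set_pvalue(observed, wm, background, b_draws=199, seed=2)
        occ_obs = expected_occupancy("AAAA", wm, MODEL)
        occ_null = expected_occupancy("CCCC", wm, MODEL)
        assert occ_obs > occ_null
        assert p == pytest.approx(1 / 200)

    def test_oversized_region_rejected(self):
        wm = WeightMatrix("m", [[1, 1, 1, 1]])
        with pytest.raises(ValueError, match="5000"):
            region_set_pvalue(["A" * 5001], wm, ["ACGT" * 2000], b_draws=9)


class TestBH:
    def test_hand_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        # step-up: p_(i) * n / i with enforced monotonicity => all 0.04
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_hand_step_up_general(self):
        p = [0.005, 0.04, 0.03, 0.8]
        got = bh_adjust(p)
        # manual: sorted (0.005,0.03,0.04,0.8) -> (0.02,0.053..,0.053..,0.8)
        assert got == pytest.approx([0.02, 0.05333333, 0.05333333, 0.8], rel=1e-6)

    def test_single_and_equal_values(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(1e-6, 1, size=10)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDivergenceMap:
    def test_equal_ps_unflagged(self):
        recs = divergence_map({"m": {"human": 0.1, "chimpanzee": 0.1, "macaque": 0.1}})
        assert recs[0].delta_hc == 0 and recs[0].delta_hm == 0
        assert not recs[0].consistent

    def test_human_gain_arithmetic(self):
        recs = divergence_map(
            {"m": {"human": 1e-3, "chimpanzee": 0.1, "macaque": 0.1}}
        )
        assert recs[0].delta_hc == pytest.approx(2.0)
        assert recs[0].delta_hm == pytest.approx(2.0)
        assert recs[0].consistent and recs[0].direction == "human_gain"

    def test_flags_equal_brute_force_rule(self, rng):
        per_motif = {
            f"m{i}": {
                "human": float(rng.uniform(1e-4, 1)),
                "chimpanzee": float(rng.uniform(1e-4, 1)),
                "macaque": float(rng.uniform(1e-4, 1)),
            }
            for i in range(200)
        }
        recs = divergence_map(per_motif, threshold=1.0)
        for r in recs:
            ps = per_motif[r.motif_id]
            d1 = -math.log10(ps["human"]) + math.log10(ps["chimpanzee"])
            d2 = -math.log10(ps["human"]) + math.log10(ps["macaque"])
            expect = (d1 * d2 > 0) and min(abs(d1), abs(d2)) >= 1.0
            assert r.consistent == expect

    def test_zero_p_clamped_and_flagged(self):
        recs = divergence_map({"m": {"human": 0.0, "chimpanzee": 0.5, "macaque": 0.5}})
        assert recs[0].clamped and math.isfinite(recs[0].delta_hc)

    def test_null_fixture_false_flag_rate_under_five_percent(self, rng):
        """With no planted differences, < 5% of motifs are flagged."""
        per_motif = {}
        for i in range(500):
            base = float(rng.uniform(0.05, 1))
            per_motif[f"m{i}"] = {
                sp: min(1.0, max(1e-6, base * float(rng.lognormal(0, 0.3))))
                for sp in ("human", "chimpanzee", "macaque")
            }
        recs = divergence_map(per_motif, threshold=1.0)
        assert sum(r.consistent for r in recs) / len(recs) < 0.05


class TestEmpiricalDirectionalP:
    def test_never_exceeded_gives_one_over_n_plus_one(self):
        pool = list(range(100))
        p = empirical_directional_p(
            (50.0, 50.0), pool, 5, lambda s: (0.0, 0.0), reps=4, n=1000, seed=0
        )
        assert p == pytest.approx(1 / 4001)

    def test_null_observed_zero_mostly_insignificant(self, rng):
        pool = [float(x) for x in rng.normal(0, 1, 200)]

        def stat(sample):
            return float(np.mean(sample)), float(np.mean(sample))

        p = empirical_directional_p((0.0, 0.0), pool, 10, stat, reps=2, n=200, seed=1)
        assert p > 0.1

    def test_exhaustive_tiny_pool(self):
        """Pool of 3, samples of 2: only 3 subsets exist; the count of
        exceeding draws matches full enumeration."""
        import itertools

        pool = [1.0, 2.0, 10.0]

        def stat(sample):
            s = sum(sample)
            return s, s

        observed = (11.0, 11.0)
        subsets = list(itertools.combinations(pool, 2))
        exceeds = sum(1 for s in subsets if sum(s) >= 11.0)  # only {1,10},{2,10}... sums 11,12
        reps, n = 4, 300
        p = empirical_directional_p(observed, pool, 2, stat, reps=reps, n=n, seed=3)
        # expected proportion of qualifying subsets is exceeds/3
        assert abs(p - exceeds / 3) < 0.06

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            empirical_directional_p((0, 0), [1, 2], 1, lambda s: (0, 0), n=0)


class TestMdrScreen:
    BACKGROUND = ["".join("ACGT"[(i * 7 + j) % 4] for j in range(400)) for i in range(8)]

    def test_identical_sequences_no_flags(self):
        seq = "ACGTTGCA" * 20
        trip = RegionTriplet("r", seq, seq, seq)
        wm = WeightMatrix("m", [[9, 0, 1, 0], [0, 8, 0, 2]])
        out = mdr_screen(trip, [wm], self.BACKGROUND, b_draws=99)
        assert all(rec["call"] == "none" for rec in out)

    def test_planted_single_base_gain_flagged(self, rng):
        """A strong motif site present only in the human sequence (one
        central base difference) is called a human-specific gain."""
        wm = WeightMatrix(
            "rfx_like",
            [[0, 0, 18, 0], [0, 0, 0, 18], [0, 0, 0, 18], [0, 0, 18, 0],
             [0, 18, 0, 0], [0, 18, 0, 0], [18, 0, 0, 0], [0, 0, 0, 18],
             [0, 0, 18, 0], [0, 0, 18, 0]],
        )
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        site = wm.consensus()  # GTTGCCATGG
        human = base[:95] + site + base[105:]
        broken = site[:5] + "A" + site[6:]
        chimp = base[:95] + broken + base[105:]
        trip = RegionTriplet("r", human, chimp, chimp)
        # promoter-like background: random sequence seeded with degenerate
        # (singly mutated) motif instances, so a broken site is unremarkable
        background = []
        for i in range(20):
            b = "".join("ACGT"[k] for k in rng.integers(0, 4, 400))
            pos = int(rng.integers(0, 10))
            mut = site[:pos] + "ACGT"[int(rng.integers(0, 4))] + site[pos + 1 :]
            ins = int(rng.integers(0, 390))
            background.append(b[:ins] + mut + b[ins + 10 :])
        out = mdr_screen(trip, [wm], background, b_draws=199, seed=4)
        assert out[0]["call"] == "human_gain"
        assert out[0]["p_human"] < 0.05 <= out[0]["p_chimpanzee"]

    def test_empty_motif_set(self):
        trip = RegionTriplet("r", "ACGT" * 10, "ACGT" * 10, "ACGT" * 10)
        assert mdr_screen(trip, [], self.BACKGROUND) == []

    def test_oversized_triplet_rejected(self):
        with pytest.raises(ValueError, match="5000"):
            RegionTriplet("r", "A" * 6000, "A" * 10, "A" * 10)


class TestOrthologousIdentity:
    def test_identical_sequences(self):
        assert orthologous_identity("A" * 100, "A" * 100) == 100.0

    def test_one_substitution(self):
        a = "A" * 100
        b = "A" * 50 + "C" + "A" * 49
        assert orthologous_identity(a, b) == pytest.approx(99.0)

    def test_gap_columns_excluded(self):
        assert orthologous_identity("AC-GT", "ACCGT") == 100.0

    def test_no_aligned_columns_rejected(self):
        with pytest.raises(ValueError):
            orthologous_identity("---", "AAA")

    def test_generator_substitution_rate_recovered(self, small_trio):
        """Mean identity of planted regions matches 100*(1 - r) within
        2 SE of the binomial expectation."""
        trio = small_trio
        rate = trio.config.sub_rate["chimpanzee"]
        idents, total_bp = [], 0
        for r in trio.truth.itertuples():
            h = trio.genomes["human"][r.chrom][r.start : r.end]
            cs = trio.ref_to_native("chimpanzee", r.chrom, int(r.start))
            ce = trio.ref_to_native("chimpanzee", r.chrom, int(r.end))
            c = trio.genomes["chimpanzee"][r.chrom][cs:ce]
            if len(h) == len(c):
                idents.append(orthologous_identity(h, c) * len(h) / 100)
                total_bp += len(h)
        match_rate = sum(idents) / total_bp
        expected = 1 - rate
        se = math.sqrt(expected * (1 - expected) / total_bp)
        assert abs(match_rate - expected) < 3 * se + 1e-3
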