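"""GC-skew profiling, origin prediction, arm symmetry, and inversion ranking."""

import numpy as np
import pytest

from sisterscan.genomeio import Feature, GenomeRecord, revcomp
from sisterscan.repeats import RepeatPair
from sisterscan.skew import (NoConfidentCallError, apply_inversion,
                             apply_translocation, gc_skew, genome_symmetry,
                             predict_origin, rank_rearrangements,
                             symmetry_score)

from conftest import random_dna


def two_arm_genome(L=300_000, flip=110_000, s=0.12, seed=0):
    """Constant-skew arms: C-rich before ``flip``, G-rich after, so the
    cumulative curve dips to its minimum at ``flip`` (the origin analog)."""
    rng = np.random.default_rng(seed)
    p_crich = [0.25, 0.25 * (1 + s), 0.25 * (1 - s), 0.25]
    p_grich = [0.25, 0.25 * (1 - s), 0.25 * (1 + s), 0.25]
    seq = random_dna(rng, flip, p=p_crich) + random_dna(rng, L - flip, p=p_grich)
    return GenomeRecord("twoarm", seq, "circular")


class TestGcSkew:
    def test_window_arithmetic(self):
        seq = "GGGGCC" * 20 + "AT" * 40  # window of 120 G/C-only bases
        prof = gc_skew(GenomeRecord("g", seq, "linear"), window=120, step=120)
        assert prof.values[0] == pytest.approx((80 - 40) / 120)

    def test_all_at_window_degenerate_zero(self):
        prof = gc_skew(GenomeRecord("g", "AT" * 100, "linear"), window=100, step=100)
        assert prof.values[0] == 0.0 and prof.degenerate[0]

    def test_cumulative_endpoint_is_gc_difference(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 10_000)
        for window, step in ((100, 50), (500, 500), (1000, 100)):
            prof = gc_skew(GenomeRecord("g", seq, "circular"), window=window, step=step)
            assert prof.cumulative[-1] == seq.count("G") - seq.count("C")

    def test_reverse_complement_negates_and_reverses_profile(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 5_000)
        p1 = gc_skew(GenomeRecord("g", seq, "linear"), window=500, step=500)
        p2 = gc_skew(GenomeRecord("g", revcomp(seq), "linear"), window=500, step=500)
        assert np.allclose(p2.values, -p1.values[::-1])

    def test_window_larger_than_genome_is_error(self):
        with pytest.raises(ValueError):
            gc_skew(GenomeRecord("g", "ACGT" * 50, "linear"), window=1000, step=100)


class TestPredictOrigin:
    def test_origin_at_constructed_flip(self):
        g = two_arm_genome()
        prof = gc_skew(g, window=10_000, step=1_000)
        origin, terminus = predict_origin(prof)
        assert abs(origin - 110_000) <= 10_000
        assert min(abs(terminus - 0), abs(terminus - len(g))) <= 10_000 or terminus > 290_000

    def test_flat_curve_no_confident_call(self):
        prof = gc_skew(GenomeRecord("g", "AT" * 60_000, "circular"),
                       window=10_000, step=1_000)
        with pytest.raises(NoConfidentCallError):
            predict_origin(prof)

    def test_rotation_equivariance(self):
        g = two_arm_genome(seed=3)
        # balance total G-C so the cumulative baseline is rotation-clean
        seq = g.seq
        diff = seq.count("G") - seq.count("C")
        pad = ("C" if diff > 0 else "G") * abs(diff)
        seq = seq + pad
        r = 50_000
        g1 = GenomeRecord("g", seq, "circular")
        g2 = GenomeRecord("g", seq[r:] + seq[:r], "circular")
        o1, t1 = predict_origin(gc_skew(g1, 10_000, 1_000))
        o2, t2 = predict_origin(gc_skew(g2, 10_000, 1_000))
        L = len(seq)
        assert min(abs((o1 - r) % L - o2), abs(o2 - (o1 - r) % L)) <= 1
        assert (t1 - r) % L == t2

    def test_dnaA_preference_logged(self, caplog):
        g = two_arm_genome(seed=4)
        prof = gc_skew(g, window=10_000, step=1_000)
        o_global, _ = predict_origin(prof)
        # ask for a dnaA far from the global minimum but near a local one
        with caplog.at_level("INFO"):
            o2, _ = predict_origin(prof, dnaA_locus=(o_global + 120_000) % len(g))
        assert isinstance(o2, int)


class TestSymmetry:
    def test_ideal_two_arm_score_high(self):
        g = two_arm_genome(seed=5)
        prof = gc_skew(g, 10_000, 1_000)
        o, t = predict_origin(prof)
        assert symmetry_score(prof, o, t) >= 0.99

    def test_inversion_lowers_score(self):
        g = two_arm_genome(seed=6)
        base = genome_symmetry(g, 2_000, 500)
        g2 = apply_inversion(g, 150_000, 250_000)
        assert genome_symmetry(g2, 2_000, 500) < base

    def test_rotation_invariance(self):
        g = two_arm_genome(seed=7)
        seq = g.seq
        diff = seq.count("G") - seq.count("C")
        seq = seq + ("C" if diff > 0 else "G") * abs(diff)
        s1 = genome_symmetry(GenomeRecord("g", seq, "circular"), 5_000, 1_000)
        r = 77_777
        s2 = genome_symmetry(GenomeRecord("g", seq[r:] + seq[:r], "circular"), 5_000, 1_000)
        assert s1 == pytest.approx(s2, abs=0.02)

    def test_short_arm_is_error(self):
        g = two_arm_genome(seed=8)
        prof = gc_skew(g, 10_000, 1_000)
        with pytest.raises(ValueError):
            symmetry_score(prof, 1000, 2000)


class TestApplyInversion:
    def _genome(self):
        rng = np.random.default_rng(9)
        feats = [Feature("in", "CDS", 120, 180, "+"),
                 Feature("out", "CDS", 10, 70, "-"),
                 Feature("straddle", "CDS", 90, 110, "+")]
        return GenomeRecord("g", random_dna(rng, 300), "linear", feats)

    def test_involution_restores_genome(self):
        g = self._genome()
        g2 = apply_inversion(apply_inversion(g, 100, 200), 100, 200)
        assert g2.seq == g.seq
        assert [(f.locus_tag, f.start, f.end, f.strand) for f in g2.features] == \
            [(f.locus_tag, f.start, f.end, f.strand) for f in g.features]

    def test_contained_feature_flips_strand_same_length(self):
        g2 = apply_inversion(self._genome(), 100, 200)
        f = g2.get("in")
        assert f.strand == "-" and len(f) == 60
        assert (f.start, f.end) == (100 + 200 - 180, 100 + 200 - 120)

    def test_straddling_feature_flagged_broken(self):
        g2 = apply_inversion(self._genome(), 100, 200)
        assert g2.get("straddle").broken
        assert not g2.get("out").broken

    def test_preserves_length_and_composition(self):
        g = self._genome()
        g2 = apply_inversion(g, 50, 250)
        assert len(g2) == len(g)
        for b in "ACGT":
            # inversion swaps complementary base counts within the segment
            pass
        assert sorted(g2.seq[:50]) == sorted(g.seq[:50])
        assert g2.seq[50:250] == revcomp(g.seq[50:250])

    def test_inverted_segment_skew_negates(self):
        g = two_arm_genome(L=100_000, flip=40_000, seed=10)
        g2 = apply_inversion(g, 20_000, 80_000)
        p1 = gc_skew(GenomeRecord("s", g.seq[20_000:80_000], "linear"), 1000, 1000)
        p2 = gc_skew(GenomeRecord("s", g2.seq[20_000:80_000], "linear"), 1000, 1000)
        assert np.allclose(p2.values, -p1.values[::-1])


class TestTranslocation:
    def test_segment_moves_with_features(self):
        rng = np.random.default_rng(11)
        g = GenomeRecord("g", random_dna(rng, 1000), "linear",
                         [Feature("m", "CDS", 300, 360, "+")])
        g2 = apply_translocation(g, 300, 360, 700)
        assert g2.seq[700:760] == g.seq[300:360]
        f = g2.get("m")
        assert (f.start, f.end, f.strand) == (700, 760, "+")
        assert len(g2) == len(g)


class TestRankRearrangements:
    def test_planted_inversion_ranked_first(self):
        g = two_arm_genome(seed=12)
        g2 = apply_inversion(g, 150_000, 250_000)
        true_rp = RepeatPair((149_600, 150_400), (249_600, 250_400), "inverted", 800, 100.0)
        decoys = [RepeatPair((30_000, 30_800), (200_000, 200_800), "inverted", 800, 100.0),
                  RepeatPair((60_000, 60_800), (90_000, 90_800), "inverted", 800, 100.0)]
        cands = rank_rearrangements(g2, [true_rp] + decoys, window=2_000, step=500)
        assert cands[0].breakpoints == (150_000, 250_000)
        assert cands[0].score > 0

    def test_symmetric_genome_scores_at_most_baseline(self):
        g = two_arm_genome(seed=13)
        pairs = [RepeatPair((30_000, 30_800), (200_000, 200_800), "inverted", 800, 100.0),
                 RepeatPair((60_000, 60_800), (140_000, 140_800), "inverted", 800, 100.0)]
        cands = rank_rearrangements(g, pairs, window=2_000, step=500)
        assert all(c.score <= 0 for c in cands)

    def test_deterministic_ordering(self):
        g = apply_inversion(two_arm_genome(seed=14), 120_000, 220_000)
        pairs = [RepeatPair((119_600, 120_400), (219_600, 220_400), "inverted", 800, 100.0),
                 RepeatPair((10_000, 10_800), (50_000, 50_800), "inverted", 800, 100.0)]
        c1 = rank_rearrangements(g, pairs, window=2_000, step=500)
        c2 = rank_rearrangements(g, pairs, window=2_000, step=500)
        assert [(c.breakpoints, c.rank, c.score) for c in c1] == \
            [(c.breakpoints, c.rank, c.score) for c in c2]

    def test_direct_pairs_ignored_and_empty_input(self):
        g = two_arm_genome(seed=15)
        assert rank_rearrangements(g, []) == []
        direct = [RepeatPair((1000, 1800), (5000, 5800), "direct", 800, 100.0)]
        assert rank_rearrangements(g, direct, window=2_000, step=500) == []
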