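"""Codon-aware SNP classification, region summaries, and gene-pair metrics."""

import numpy as np
import pytest

from sisterscan.genomeio import Feature, GenomeRecord, revcomp
from sisterscan.variants import (SNPRecord, classify_snp, classify_snps,
                                 compare_marker_genes, gene_pair_diff,
                                 region_summary)

from conftest import random_dna


def snp_at(genome, pos, alt):
    return SNPRecord(posA=pos, posB=pos, baseA=genome.seq[pos], baseB=alt)


class TestClassifySnp:
    # toy CDS at [10,31): ATG AAA TGG CCC GAA TAA
    @pytest.mark.parametrize("pos,alt,klass,aaA,aaB", [
        (15, "G", "synonymous", "K", "K"),      # AAA->AAG
        (13, "G", "nonsynonymous", "K", "E"),   # AAA->GAA
        (18, "A", "nonsense", "W", "*"),        # TGG->AGG? no: pos 18 is codon 2 start
    ])
    def test_codon_examples_forward(self, toy_cds_genome, pos, alt, klass, aaA, aaB):
        if klass == "nonsense":
            # TGG -> TGA: third base of codon 2 (positions 16..18)
            pos, alt = 18, "A"
        rec = classify_snp(snp_at(toy_cds_genome, pos, alt), toy_cds_genome)
        assert rec.klass == klass
        assert (rec.aaA, rec.aaB) == (aaA, aaB)

    def test_intergenic_and_context(self, toy_cds_genome):
        rec = classify_snp(snp_at(toy_cds_genome, 2, "G"), toy_cds_genome)
        assert rec.klass == "intergenic" and rec.context == "intergenic"

    def test_rna_context(self):
        g = GenomeRecord("g", "A" * 50, "linear",
                         [Feature("r16", "rRNA", 10, 40, "+", "16S ribosomal RNA")])
        rec = classify_snp(SNPRecord(20, 20, "A", "G"), g)
        assert rec.klass == "rna"

    def test_strand_invariance(self, toy_cds_genome):
        """Classifying on the '-' strand equals classifying the reverse
        complement coordinate frame."""
        fwd = toy_cds_genome
        L = len(fwd.seq)
        cds = fwd.features[0]
        rev_feat = Feature("cds1", "CDS", L - cds.end, L - cds.start, "-", "toy")
        rev = GenomeRecord("toyrc", revcomp(fwd.seq), "linear", [rev_feat])
        for pos, alt in [(13, "G"), (15, "G"), (18, "A"), (2, "C")]:
            r1 = classify_snp(snp_at(fwd, pos, alt), fwd)
            pos_rc = L - 1 - pos
            alt_rc = revcomp(alt)
            r2 = classify_snp(snp_at(rev, pos_rc, alt_rc), rev)
            assert r1.klass == r2.klass
            if r1.context == "CDS":
                assert (r1.aaA, r1.aaB) == (r2.aaA, r2.aaB)

    def test_multi_hit_codon_class(self, toy_cds_genome):
        snps = [snp_at(toy_cds_genome, 13, "G"), snp_at(toy_cds_genome, 14, "C")]
        recs = classify_snps(snps, toy_cds_genome)
        assert all(r.klass == "multi_hit_codon" for r in recs)

    def test_overlapping_cds_one_record_per_locus(self):
        seq = "T" * 5 + "ATGAAACCCTAA" + "T" * 20
        f1 = Feature("a", "CDS", 5, 17, "+")
        f2 = Feature("b", "CDS", 8, 35, "+")
        g = GenomeRecord("g", seq, "linear", [f1, f2])
        recs = classify_snps([SNPRecord(10, 10, seq[10], "T")], g)
        assert {r.locus_tag for r in recs} == {"a", "b"}

    def test_unframed_cds_flagged_ambiguous_not_dropped(self):
        g = GenomeRecord("g", "T" * 5 + "ATGAAACC" + "T" * 20, "linear",
                         [Feature("x", "CDS", 5, 13, "+")])
        recs = classify_snps([SNPRecord(7, 7, "G", "A")], g)
        assert len(recs) == 1 and recs[0].ambiguous

    def test_agrees_with_planting_oracle_on_fixture(self, hotspot_pair):
        A, B, truth, _ = hotspot_pair
        snps = [SNPRecord(posA=s.posA, posB=s.posB, baseA=s.baseA, baseB=s.baseB)
                for s in truth.snps]
        recs = classify_snps(snps, A)
        by_pos = {s.posA: s.klass for s in truth.snps}
        single_hit = [r for r in recs if r.klass != "multi_hit_codon"]
        assert single_hit, "fixture should contain single-hit codons"
        for r in single_hit:
            assert r.klass == by_pos[r.posA]


class TestRegionSummary:
    def test_empty_region_all_zero(self):
        rs = region_summary([], (0, 100), label="empty")
        assert (rs.n_snps, rs.n_syn, rs.n_nonsyn, rs.n_other) == (0, 0, 0, 0)

    def test_totals_partition_snp_count(self, hotspot_pair):
        A, _B, truth, _ = hotspot_pair
        snps = classify_snps(
            [SNPRecord(s.posA, s.posB, s.baseA, s.baseB) for s in truth.snps], A)
        rs = region_summary(snps, (0, len(A)), label="genome")
        assert rs.n_snps == len(snps)
        assert rs.n_snps == rs.n_syn + rs.n_nonsyn + rs.n_other

    def test_hotspot_and_background_counts(self, hotspot_pair):
        A, _B, truth, _ = hotspot_pair
        snps = classify_snps(
            [SNPRecord(s.posA, s.posB, s.baseA, s.baseB) for s in truth.snps], A)
        hot = region_summary(snps, truth.regions_A["hotspot"], label="hotspot")
        bg = region_summary(snps, truth.regions_A["background"], label="background")
        assert (hot.n_snps, hot.n_nonsyn) == (70, 67)
        assert (bg.n_snps, bg.n_nonsyn) == (25, 7)

    def test_locus_span_region(self, toy_cds_genome):
        rs = region_summary([SNPRecord(12, 12, "A", "G", klass="synonymous")],
                            ("cds1", "cds1"), genomeA=toy_cds_genome)
        assert rs.n_snps == 1

    def test_unknown_locus_is_error(self, toy_cds_genome):
        with pytest.raises(KeyError):
            region_summary([], ("nope", "cds1"), genomeA=toy_cds_genome)


class TestGenePairDiff:
    def test_identical_genes(self):
        d = gene_pair_diff("ATGAAACCCTAA", "ATGAAACCCTAA")
        assert (d.nt_diffs, d.aa_diffs) == (0, 0)
        assert d.nt_pct_id == 100.0 and d.aa_pct_id == 100.0

    def test_known_differences(self):
        rng = np.random.default_rng(8)
        from sisterscan.simulate import SENSE_CODONS
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, 200)]
        a = "ATG" + "".join(codons) + "TAA"
        # plant 5 nonsynonymous first-position changes in distinct codons
        b = list(a)
        changed = 0
        for ci in range(10, 200, 13):
            p = 3 + ci * 3
            old = b[p]
            for alt in "ACGT":
                if alt != old:
                    cod = "".join(b[p:p + 3]).replace(old, alt, 1)
                    from Bio.Seq import Seq
                    if cod not in ("TAA", "TAG", "TGA") and \
                            str(Seq(cod).translate()) != str(Seq("".join(b[p:p+3])).translate()):
                        b[p] = alt
                        changed += 1
                        break
            if changed == 5:
                break
        b = "".join(b)
        d = gene_pair_diff(a, b)
        assert d.nt_diffs == 5 and d.aa_diffs == 5
        assert d.nt_len_aligned == len(a)

    def test_equal_length_reduces_to_positionwise(self):
        a = "ATGAAAAAACCCGGGTAA"
        b = "ATGAAAAAACCCGGCTAA"
        d = gene_pair_diff(a, b)
        assert d.nt_diffs == sum(1 for x, y in zip(a, b) if x != y)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            gene_pair_diff("", "ATG")


class TestMarkerGenes:
    def _genome_with_16s(self, gid, seq16):
        g = GenomeRecord(gid, "T" * 10 + seq16 + "T" * 10, "linear",
                         [Feature(f"{gid}_16S", "rRNA", 10, 10 + len(seq16), "+",
                                  "16S ribosomal RNA")])
        return g

    def test_identical_markers_zero_differences(self):
        rng = np.random.default_rng(9)
        s = random_dna(rng, 1500)
        mat = compare_marker_genes([self._genome_with_16s("a", s),
                                    self._genome_with_16s("b", s)])
        assert mat.loc["a", "b"] == 0

    def test_insertion_masked(self):
        rng = np.random.default_rng(10)
        s = random_dna(rng, 1500)
        ins = random_dna(rng, 100)
        s2 = s[:50] + ins + s[50:]  # 5'-proximal insertion in one copy
        g1, g2 = self._genome_with_16s("a", s), self._genome_with_16s("b", s2)
        masked = compare_marker_genes([g1, g2], mask_insertions=True)
        unmasked = compare_marker_genes([g1, g2], mask_insertions=False)
        assert masked.loc["a", "b"] == 0
        assert unmasked.loc["a", "b"] == 100

    def test_substitutions_counted_with_masking(self):
        rng = np.random.default_rng(11)
        s = random_dna(rng, 1500)
        s2 = list(s)
        for i in range(0, 1000, 100):
            s2[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s2[i]]
        mat = compare_marker_genes([self._genome_with_16s("a", s),
                                    self._genome_with_16s("b", "".join(s2))])
        assert mat.loc["a", "b"] == 10

    def test_genome_without_marker_omitted(self, caplog):
        g1 = self._genome_with_16s("a", random_dna(np.random.default_rng(1), 1500))
        g2 = GenomeRecord("nomarker", "ACGT" * 100, "linear")
        with caplog.at_level("WARNING"):
            mat = compare_marker_genes([g1, g2])
        assert list(mat.index) == ["a"]
        assert "nomarker" in caplog.text
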