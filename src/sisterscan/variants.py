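"""Codon-aware SNP classification and gene-pair difference metrics.

Synonymy is judged against the genome-A codon with the single alternate base
substituted (no mutational-pathway assumption); codons carrying more than one
SNP get the dedicated ``multi_hit_codon`` class instead of an arbitrary
pathway choice, and nonsense changes are reported separately with an option
to fold them into the non-synonymous count for two-way summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import Seq

from .align import banded_global
from .genomeio import Feature, GenomeRecord, revcomp, translate_cds

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")

CODING_CLASSES = ("synonymous", "nonsynonymous", "nonsense", "multi_hit_codon")


@dataclass
class SNPRecord:
    """One substitution with optional codon context and synonymy class."""

    posA: int
    posB: int
    baseA: str
    baseB: str
    context: Optional[str] = None  # 'CDS' | 'intergenic' | 'RNA'
    locus_tag: Optional[str] = None
    codon_index: Optional[int] = None
    codon_pos: Optional[int] = None
    codonA: Optional[str] = None
    codonB: Optional[str] = None
    aaA: Optional[str] = None
    aaB: Optional[str] = None
    klass: Optional[str] = None
    ambiguous: bool = False


@dataclass
class RegionSummary:
    region: str
    intervals: list[tuple[int, int]]
    n_snps: int
    n_syn: int
    n_nonsyn: int
    n_other: int
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        assert self.n_snps == self.n_syn + self.n_nonsyn + self.n_other


@dataclass
class GenePairDiff:
    locusA: str
    locusB: str
    nt_len_aligned: int
    nt_diffs: int
    aa_len_aligned: int
    aa_diffs: int

    @property
    def nt_pct_id(self) -> float:
        return 100.0 * (self.nt_len_aligned - self.nt_diffs) / self.nt_len_aligned

    @property
    def aa_pct_id(self) -> float:
        return 100.0 * (self.aa_len_aligned - self.aa_diffs) / self.aa_len_aligned


def _containing_features(genome: GenomeRecord, pos: int, ftype: str):
    return [f for f in genome.features if f.ftype == ftype and f.start <= pos < f.end]


def _codon_fields(feat: Feature, genome: GenomeRecord, posA: int, baseB: str):
    """Codon context of a substitution inside a simple CDS (strand-aware)."""
    if feat.strand == "+":
        offset = posA - feat.start
        alt = baseB
    else:
        offset = feat.end - 1 - posA
        alt = baseB.translate(_COMP)
    codon_index, codon_pos = divmod(offset, 3)
    cds_nt = genome.feature_seq(feat)
    codonA = cds_nt[codon_index * 3: codon_index * 3 + 3]
    codonB = codonA[:codon_pos] + alt + codonA[codon_pos + 1:]
    return codon_index, codon_pos, codonA, codonB


def _aa(codon: str, codon_index: int) -> str:
    if codon_index == 0 and codon in ("ATG", "GTG", "TTG"):
        return "M"
    return str(Seq(codon).translate(table=11))


def classify_snps(snps: list[SNPRecord], genomeA: GenomeRecord,
                  genomeB: GenomeRecord = None) -> list[SNPRecord]:
    """Fill the synonymy class of each SNP against genome A's annotation.

    A SNP inside two overlapping CDSs yields one record per locus_tag. CDSs
    whose length is not divisible by 3 flag their SNPs ambiguous rather than
    dropping them. Codons carrying more than one SNP of the input set are
    classed multi_hit_codon.
    """
    out: list[SNPRecord] = []
    per_codon: dict[tuple[str, int], list[int]] = {}
    for snp in snps:
        cdss = [f for f in _containing_features(genomeA, snp.posA, "CDS")
                if not (f.pseudo or f.codon_excluded)]
        if not cdss:
            rnas = (_containing_features(genomeA, snp.posA, "rRNA")
                    + _containing_features(genomeA, snp.posA, "tRNA"))
            if rnas:
                out.append(replace(snp, context="RNA", klass="rna",
                                   locus_tag=rnas[0].locus_tag))
            else:
                out.append(replace(snp, context="intergenic", klass="intergenic"))
            continue
        for feat in cdss:
            if len(feat) % 3:
                log.warning("CDS %s length %d not divisible by 3; SNP at %d flagged ambiguous",
                            feat.locus_tag, len(feat), snp.posA)
                out.append(replace(snp, context="CDS", locus_tag=feat.locus_tag,
                                   klass="nonsynonymous", ambiguous=True))
                continue
            ci, cp, codonA, codonB = _codon_fields(feat, genomeA, snp.posA, snp.baseB)
            aaA, aaB = _aa(codonA, ci), _aa(codonB, ci)
            if aaA == aaB:
                klass = "synonymous"
            elif aaB == "*":
                klass = "nonsense"
            else:
                klass = "nonsynonymous"
            rec = replace(snp, context="CDS", locus_tag=feat.locus_tag,
                          codon_index=ci, codon_pos=cp, codonA=codonA,
                          codonB=codonB, aaA=aaA, aaB=aaB, klass=klass)
            per_codon.setdefault((feat.locus_tag, ci), []).append(len(out))
            out.append(rec)
    for (_tag, _ci), idxs in per_codon.items():
        if len(idxs) > 1:
            for i in idxs:
                out[i] = replace(out[i], klass="multi_hit_codon")
    return out


def classify_snp(snp: SNPRecord, genomeA: GenomeRecord,
                 genomeB: GenomeRecord = None) -> SNPRecord:
    """Classify one SNP in isolation (no multi-hit detection possible)."""
    return classify_snps([snp], genomeA, genomeB)[0]


def resolve_region(genomeA: GenomeRecord, region_spec) -> tuple[int, int]:
    """An explicit (start, end) interval, or an inclusive (from_locus,
    to_locus) span from the 5'-most to the 3'-most coordinate of the two."""
    if isinstance(region_spec, tuple) and all(isinstance(x, int) for x in region_spec):
        return region_spec
    lo_tag, hi_tag = region_spec
    f1 = genomeA.get(lo_tag)
    f2 = genomeA.get(hi_tag)
    return min(f1.start, f2.start), max(f1.end, f2.end)


def region_summary(snps: list[SNPRecord], region_spec, genomeA: GenomeRecord = None,
                   label: str = "region", fold_nonsense: bool = True) -> RegionSummary:
    """Count synonymy classes over SNPs whose genome-A position is in the region.

    With ``fold_nonsense`` (default) nonsense changes count as non-synonymous,
    giving the two-way synonymous / non-synonymous split; otherwise they fall
    into ``n_other``.
    """
    if genomeA is None and not (isinstance(region_spec, tuple)
                                and all(isinstance(x, int) for x in region_spec)):
        raise ValueError("locus-based region spec requires genomeA")
    start, end = resolve_region(genomeA, region_spec) if genomeA else region_spec
    inside = [s for s in snps if start <= s.posA < end]
    n_syn = sum(1 for s in inside if s.klass == "synonymous")
    nonsyn_classes = {"nonsynonymous", "nonsense"} if fold_nonsense else {"nonsynonymous"}
    n_nonsyn = sum(1 for s in inside if s.klass in nonsyn_classes)
    n_other = len(inside) - n_syn - n_nonsyn
    notes = [f"multi_hit codon {s.locus_tag}:{s.codon_index}" for s in inside
             if s.klass == "multi_hit_codon"]
    return RegionSummary(label, [(start, end)], len(inside), n_syn, n_nonsyn,
                         n_other, sorted(set(notes)))


def _pairwise_diff(sa: str, sb: str, band: Optional[int] = None,
                   count_gaps: bool = True, free_ends: bool = True) -> tuple[int, int]:
    """Aligned length and differences under (end-free) global alignment.

    Equal-length inputs at >=90% positionwise identity skip the dynamic
    program (the alignment provably reduces to positionwise comparison
    there). Differences are mismatch plus, when ``count_gaps``, internal gap
    columns; free end overhangs are never counted.
    """
    if len(sa) == len(sb) and sa and sb:
        mism = sum(1 for x, y in zip(sa, sb) if x != y)
        if mism <= 0.10 * len(sa):
            return len(sa), mism
    band_eff = band if band is not None else max(len(sa), len(sb))
    _, edits = banded_global(sa, sb, band=band_eff, free_ends=free_ends)
    # strip end overhangs
    core = list(edits)
    if core and core[0].op in ("insA", "insB"):
        core = core[1:]
    if core and core[-1].op in ("insA", "insB"):
        core = core[:-1]
    length = sum(e.length for e in core)
    mism = sum(e.length for e in core if e.op == "mismatch")
    gaps = sum(e.length for e in core if e.op in ("insA", "insB"))
    return length, mism + (gaps if count_gaps else 0)


def gene_pair_diff(cdsA: str, cdsB: str, locusA: str = "A", locusB: str = "B") -> GenePairDiff:
    """Nucleotide- and protein-level differences between two orthologous CDSs.

    Sequences are given in CDS orientation. Both the nucleotide sequences and
    their translations (bacterial code) are compared under end-free global
    alignment; differences are mismatch plus gap columns.
    """
    if not cdsA or not cdsB:
        raise ValueError("empty sequence")
    nt_len, nt_diffs = _pairwise_diff(cdsA.upper(), cdsB.upper())
    aaA = translate_cds(cdsA.upper()) if len(cdsA) % 3 == 0 else str(Seq(cdsA.upper()).translate(table=11))
    aaB = translate_cds(cdsB.upper()) if len(cdsB) % 3 == 0 else str(Seq(cdsB.upper()).translate(table=11))
    aa_len, aa_diffs = _pairwise_diff(aaA, aaB)
    return GenePairDiff(locusA, locusB, nt_len, nt_diffs, aa_len, aa_diffs)


def _marker_seq(genome: GenomeRecord, gene_type: str) -> Optional[str]:
    for f in genome.features:
        if f.ftype == "rRNA" and gene_type.lower() in f.product.lower():
            return genome.feature_seq(f)
    return None


def compare_marker_genes(genomes: list[GenomeRecord], gene_type: str = "16S",
                         mask_insertions: bool = True):
    """Pairwise nucleotide-difference matrix of a marker gene (one copy per
    genome).

    With ``mask_insertions`` columns inside indel segments — sequence present
    in only one of the two genomes, such as 5' insertions in some 16S genes —
    are excluded, counting substitutions only. Full-length marker genes are
    compared under strict global alignment (no free ends). Genomes lacking
    the marker are omitted with a warning.
    """
    import pandas as pd

    seqs = {}
    for g in genomes:
        s = _marker_seq(g, gene_type)
        if s is None:
            log.warning("genome %s lacks a %s marker; omitted", g.id, gene_type)
        else:
            seqs[g.id] = s
    ids = list(seqs)
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, gi in enumerate(ids):
        for gj in ids[i + 1:]:
            _, d = _pairwise_diff(seqs[gi], seqs[gj], count_gaps=not mask_insertions,
                                  free_ends=False)
            mat.loc[gi, gj] = mat.loc[gj, gi] = d
    return mat


def write_snps_tsv(snps: list[SNPRecord], path: str) -> None:
    cols = ("posA", "posB", "baseA", "baseB", "context", "locus_tag",
            "codon_index", "codon_pos", "codonA", "codonB", "aaA", "aaB", "klass")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in snps:
            fh.write("\t".join("" if (v := getattr(s, c)) is None else str(v) for c in cols) + "\n")


def write_snps_vcf(snps: list[SNPRecord], genomeA: GenomeRecord, path: str) -> None:
    """Minimal VCF with genome A as the reference (INFO CLASS/LOCUS/CODON)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genomeA.id},length={len(genomeA)}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Synonymy class">\n')
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=String,Description="Containing locus_tag">\n')
        fh.write('##INFO=<ID=CODON,Number=1,Type=String,Description="Ref/alt codon">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda x: x.posA):
            info = [f"CLASS={s.klass or 'unclassified'}"]
            if s.locus_tag:
                info.append(f"LOCUS={s.locus_tag}")
            if s.codonA:
                info.append(f"CODON={s.codonA}/{s.codonB}")
            fh.write(f"{genomeA.id}\t{s.posA + 1}\t.\t{s.baseA}\t{s.baseB}\t.\t.\t"
                     + ";".join(info) + "\n")
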