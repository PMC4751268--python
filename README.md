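# sisterscan

Comparative genomics of *sister* bacterial genomes — pairs of chromosomes
that diverged so recently that they are still collinear and >99.8% identical
outside a handful of hotspots, islands, and mobile-element insertions. The
motivating system is the organohalide-respiring genus *Dehalobacter*, where
two ~3.1 Mb strains differ chiefly around the reductive-dehalogenase genes
(*rdhA*) that determine which chlorinated substrate each strain respires,
and where the excess of amino-acid-changing substitutions in that one
neighborhood is the signature of substrate-driven positive selection.

`sisterscan` is for microbial genomicists who want that whole analysis as a
tested, scriptable pipeline rather than a chain of GUI tools:

* **Collinear whole-genome alignment** — maximal exact matches seeded by
  k-mers unique in both genomes (MUM-style), maximum-weight collinear
  chaining per orientation, banded global gap closure; strain-specific
  insertions above a size threshold are reported as unaligned segments
  instead of being forced into the alignment.
* **SNP extraction and synonymy classification** — every mismatch column
  becomes a SNP record; inside a CDS the reference codon with the single
  alternate base substituted is translated (bacterial code, table 11), and
  the SNP is classed synonymous / non-synonymous / nonsense, with multi-hit
  codons in their own class. Regional summaries give the
  (synonymous, non-synonymous) counts that expose selection hotspots.
* **Identity metrics** — core identity (matches over match+mismatch columns
  of the collinear core, the ">99.8% over 2.9 Mb" style figure) and
  whole-genome identity (gap columns and unaligned segments in the
  denominator, the "~90% ANI" style figure).
* **GC skew and rearrangements** — windowed and cumulative (G−C)/(G+C)
  profiles, replication-origin/terminus calls from the cumulative curve's
  extrema (optionally steered by a *dnaA* locus), a replichore-arm mirror
  symmetry score, and ranking of inverted-repeat-mediated inversion
  scenarios by how much tentatively reverting them restores arm symmetry
  and synteny with a reference genome.
* **Repeats and IS elements** — maximal direct/inverted repeat pairs by
  seed-and-extend, insertion-sequence copy-number counting with
  identity/coverage thresholds, detection of direct repeats flanking
  candidate horizontally transferred cassettes.
* **Orthology** — reciprocal best hits from a built-in word-seeded banded
  Smith–Waterman (BLOSUM62, affine gaps, Karlin–Altschul bit scores and
  e-values), or from externally computed 12-column tabular searches.
* **Regulator census** — the protein-coding genes fewer than five gene-order
  positions from each *rdhA*-like anchor, counted into Crp/Fnr, histidine
  kinase/response regulator, MarR, and other-regulatory categories by their
  Pfam domain content (pfam_scan-style input, e-value < 0.001).
* **Synthetic sister-genome generator** — circular ancestors with planted IS
  multiplicities, rRNA-operon inverted repeats, and an anchor-gene
  neighborhood; sisters derived with exact region-specific SNP counts and
  non-synonymous fractions, islands of chosen GC content, strain-specific
  transpositions, and repeat-mediated inversions, all recorded in a truth
  table. Every downstream stage is therefore testable end to end with no
  downloads.

## Worked example

Plant the hotspot signal on a ~160 kb fixture and recover it:

```python
from sisterscan import *
from sisterscan.simulate import MutationSpec, simulate_ancestor, derive_sisters

anc = simulate_ancestor(n_genes=120, seed=7)
rdhA = anc.get("rdhA1")
spec = MutationSpec(
    regions={"hotspot": (rdhA.start - 6000, rdhA.end + 6000),
             "background": (0, 30_000)},
    n_snps_by_region={"hotspot": (70, 67 / 70), "background": (25, 7 / 25)},
    island_specs=[(8_000, 0.40, "A")],
    n_is_transpositions=(1, 2),
    seed=7,
)
A, B, truth = derive_sisters(anc, spec)

blocks, unaligned = align_genomes(A, B)
for mode in ("core", "whole"):
    rep = identity(blocks, unaligned, mode)
    print(f"{mode} identity: {rep.pct:.4f}% over {rep.aligned_len:,} columns")

snps, _ = call_snps(blocks)
recs = classify_snps(snps, A)
for label in ("hotspot", "background"):
    rs = region_summary(recs, truth.regions_A[label], label=label)
    print(f"{label}: {rs.n_snps} SNPs, {rs.n_nonsyn} non-synonymous")
```

prints

```
core identity: 99.9378% over 152,809 columns
whole identity: 92.9155% over 156,358 columns
hotspot: 70 SNPs, 67 non-synonymous
background: 25 SNPs, 7 non-synonymous
```

The core identity reflects only the planted substitutions; the whole-genome
figure is dragged down by the 8 kb low-GC island and the IS transpositions.
The hotspot's 67/70 non-synonymous excess against the background's 7/25 is
the positive-selection signature the region summary is designed to expose.
The same fixture's IS copy table (`repeats.copy_number_table`) shows the
planted strain-specific transposition as a copy-number difference between
the sisters (e.g. IS1: 10 copies in strain A, 11 in strain B).

Real data enter through `read_genbank` / `read_gff3` (annotated genomes),
`read_xmfa` (externally computed alignments), `read_search_tab` (tabular
protein searches), and `read_domtab` (pfam_scan output).

## Layout

```
src/sisterscan/
  genomeio.py      formats (FASTA/GenBank/GFF3/XMFA/tabular) + data model
  simulate.py      synthetic ancestors, sisters, truth tables
  align.py         anchors, chaining, gap closure, SNP calls, identity
  variants.py      codon-aware classification, regions, gene pairs, markers
  skew.py          GC skew, origin calls, symmetry, inversion ranking
  repeats.py       repeat pairs, IS copy numbers, flanking repeats
  orthology.py     built-in protein search + reciprocal best hits
  neighborhood.py  anchor-gene neighborhoods and regulator census
  cli.py           subcommand front end
```

See `docs/methods.md` for the models, parameter defaults, and limitations.
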