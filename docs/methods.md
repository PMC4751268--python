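# Methods

This note records the models and procedures implemented in `sisterscan`,
the defaults and why they were chosen, what the synthetic fixtures do and do
not emulate, and the numerical conventions a maintainer needs.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open on the forward strand;
strand is a flag on the feature, never a reverse-complemented stored
sequence. GenBank and GFF3 (1-based inclusive) are converted on input and
restored on output. Translation uses the bacterial code (table 11);
alternative starts (GTG, TTG) are rendered as M at position 0 only. CDS
features with compound (join) locations or nonzero phase are excluded from
codon-level analyses — they still occupy a slot in gene-order neighborhoods
— because in these chromosomes essentially all CDSs are simple, and
half-handling the exceptions would corrupt the synonymy counts silently.

## Whole-genome alignment

The aligner targets the regime it is used in: two collinear chromosomes at
≥99% core identity with localized insertions.

1. **Anchors.** Maximal exact matches seeded by k-mers (default k=20)
   occurring exactly once in each genome, counting a k-mer and its reverse
   complement together. Uniqueness removes IS elements, rRNA operons, and
   other multi-copy sequence from the seed space; extension is by exact
   base agreement, so an anchor may legitimately run through a repeat copy
   that has identical flanking context.
2. **Chaining.** Maximum-weight collinear chain (weight = anchor length)
   per orientation via a Fenwick-tree sweep, O(n log n). Successive chain
   anchors may overlap by up to 100 bp — exact matches extend a few bases
   past a true breakpoint by chance, and at a repeat-mediated inversion
   seam the forward match continues into the inverted segment through the
   mediating repeat — and the overlap is trimmed at block construction.
   Reverse-orientation anchors are chained in reverse-complement space and
   trimmed where the forward chain already covers them; the result is one
   forward chain plus one reverse chain per inverted segment.
3. **Gap closure.** Inter-anchor gaps with both sides ≤ `max_gap` (default
   5000 bp) are aligned by banded global alignment (band 200) with unit
   scores: match +1, mismatch −1, gap −2, linear. At ≥99.9% identity the
   scoring model is immaterial; the linear gap admits an exact
   prefix-max vectorization of the row recurrence. A gap whose one side
   exceeds `max_gap` splits the block; the long side is reported unaligned
   as a `strain_specific_insertion` — the operational definition of a
   large insertion to exclude from core identity, a threshold published
   analyses rarely state. An aligned gap with both
   sides ≥ 30 bp whose match fraction falls below 0.75 is demoted to
   `below_threshold` unaligned segments: at these diagonals a unit-score
   alignment of genuinely non-orthologous sequence (e.g. different IS
   copies inserted near the same spot in the two strains) can reach ~60%
   matches, whereas truly orthologous sister gaps sit near 100%, so the
   0.75 cut cleanly separates the two populations.
4. **Circularity.** Circular genomes are aligned on the linearized sequence
   with the origin as the cut point. Sister genomes derived from one
   ancestor share the cut, so no block-spanning-the-junction machinery is
   attempted; aligning unrelated rotations should be preceded by rotating
   one genome (see Limitations).

**Identity.** Core mode divides matches by match+mismatch columns only —
the identity of the collinear core after removing insertions. Whole mode
adds gap columns and the lengths of all unaligned segments of both genomes
to the denominator, giving a whole-genome average-identity figure that
large strain-specific regions drag down. Both are reported because
published ANI-style numbers rarely state their column accounting.

## SNP classification

A SNP inside a CDS is classed against the genome-A codon with the single
alternate base substituted: codon(A) → codon(A with alt). This is
mutation-path-free; when two or more SNPs of the call set hit the same
codon, each is classed `multi_hit_codon` rather than guessing an order.
Nonsense changes are a separate class; region summaries fold them into the
non-synonymous count by default (`fold_nonsense=True`) to produce the
two-way synonymous/non-synonymous split, with the flag to keep them apart.
A CDS whose length is not divisible by 3 flags its SNPs `ambiguous` instead
of dropping them. Classification of a SNP in a '-'-strand CDS equals
classification in the reverse-complemented frame (tested property).

Gene-pair metrics use end-free global alignment (same unit scores) on the
nucleotide sequences and on the translations; for equal-length inputs at
≥90% positionwise identity the alignment provably reduces to positionwise
comparison and is computed that way. Marker-gene (16S) comparison uses
strict global alignment of full-length annotated copies; with insertion
masking on, indel columns — sequence present in only one copy, like the
5'-proximal insertions seen in some 16S genes — are excluded so the count
reflects substitutions only.

## GC skew, origin calls, and inversion ranking

Windowed skew is (G−C)/(G+C) per window (default 10 kb window, 1 kb step —
resolves Mb-scale replichore arms without base-level noise); windows with
G+C=0 report 0 with a degenerate flag. The cumulative curve is the per-base
running sum of +1 (G) / −1 (C); its endpoint equals the genome's G−C count
regardless of windowing (tested invariant). The origin call is the global
minimum of the cumulative curve and the terminus the maximum; when a dnaA
locus is supplied and lies within 50 kb of a local minimum of the
window-sampled curve, that minimum is preferred and the switch is logged.
A curve whose amplitude is below 0.1% of genome length raises
`NoConfidentCallError`.

**Arm symmetry.** The score is the Pearson correlation between the
cumulative-skew curve of arm 1 (origin→terminus) and the mirrored, negated
curve of arm 2, after resampling both to 512 points. Correlating the
cumulative curves rather than raw window increments is deliberate: for
arms of near-constant skew the increments are i.i.d. noise around a
constant and their correlation is ~0 (exactly constant arms would make it
undefined), while the cumulative curves carry the arm-scale signal, giving
~1 for ideal two-arm genomes and strictly less after an arm-scrambling
inversion. The score is a constructed operationalization of the qualitative
"more symmetrical skew" criterion and is labeled as such in reports.

**Inversion ranking.** For every inverted repeat pair the genome is
tentatively inverted between the pair's midpoints — the biological
recombination resolves somewhere inside the repeat, so the exact point is
unobservable and the midpoint is the canonical choice — and the candidate
is scored by the symmetry improvement, averaged with the anchor-chain
collinearity improvement against a reference genome when one is supplied
(equal weights). A reverted genome whose skew signal collapses entirely
(no confident origin, degenerate arms) scores −1 on the symmetry term:
reverting a true event never destroys the call. Ordering is deterministic;
ties break toward the smaller breakpoint. Translocations are supported as
explicit cut-and-reinsert edits (`apply_translocation`) with user-supplied
coordinates — the observed translocation case was identified manually via a
recombinase locus, and a genome-wide translocation search is out of scope.

## Repeats and IS copy numbers

Repeat pairs: exact 16-mer seeds in both orientations (k-mers occurring
more than 100 times are skipped as tandem noise), diagonal-run merging,
ungapped x-drop extension (match +1, mismatch −2, drop 12), and
per-diagonal union of overlapping pairs. Pairs whose two intervals overlap
(tandem cores, palindrome centers) are suppressed, and every reported pair
re-verifies at ≥ its identity threshold by alignment (tested post-hoc).

IS copies: candidate loci are seeded on both strands, then each locus is
verified by semi-global alignment of the full element (edlib); identity is
matches / element length and coverage (matches+mismatches) / element
length, with defaults min_id 0.95 and min_cov 0.90. Acceptance is greedy by
identity under a non-overlap constraint, which counts discrete copies.
The thresholds behind published per-genome IS totals are not stated
anywhere; these defaults are a declared operationalization, so exact
reproduction of such totals is a goal, not a contract. Families group
elements at ≥90% identity over ≥90% of the shorter sequence
(single-linkage).

## Orthology

The built-in search seeds on exact 5-mers shared between query and target,
then runs banded affine-gap Smith–Waterman (BLOSUM62, open 11, extend 1)
with the band spanning all shared-seed diagonals ±32. Raw scores convert to
bit scores S′ = (λS − ln K)/ln 2 with λ=0.267, K=0.041 fixed and recorded
in output headers — e-values are comparator-sensitive, so their provenance
must be explicit — and E = m·n·2^(−S′) with m the query length and n the
total target residue count. Reciprocal best hits apply the e-value filter
first, then best = lowest e-value, tie → highest bit score, tie →
lexicographic subject id; a pair is accepted when each member is the
other's filtered best. Filter-then-best is one of two defensible orders
(the alternative, best-then-filter, can only shrink the pair set) and is
noted in the output header. External tabular hits, when supplied, are
authoritative and bypass the built-in search. The within-genus cutoff is
1e-10 and the cross-genus cutoff 1e-5.

## Neighborhood census

"Fewer than five protein-coding genes up/downstream" is read literally:
members are the ≤4 CDSs on each side of the anchor in gene-order space,
regardless of strand or intergenic distance, wrapping on circular genomes;
RNA genes do not consume a position. A member counts toward a category when
it carries ≥1 qualifying domain at e-value strictly below 0.001:
Crp/Fnr ⇐ {cNMP_binding, HTH_Crp_2}; HK-RR ⇐ {HisKA, ATPase_c,
Response_reg, Trans_reg_C, PAS}; MarR ⇐ {MarR_2}; other configured
signaling domains count as OtherRegulatory. A member matching several
categories increments each (logged). The category map ships as editable
YAML because signaling-domain vocabularies evolve; the mapping is data, not
code.

## The synthetic generator and what passing tests mean

`simulate_ancestor` builds a circular chromosome of non-overlapping
random-codon CDSs (ATG … sense codons … stop), rRNA-operon placeholders as
identical ~4.5 kb copies with one inserted inverted (so an inverted repeat
pair always exists), IS families as identical copies at chosen
multiplicities (default: first family at nine copies — the extreme
multi-copy case in these genomes — then two per further family), and one
rdhA-like anchor CDS adjacent to a Crp/Fnr-style regulator CDS. Defaults of
~100–500 codons per gene and 60–200 bp intergenic spacers give a realistic
~1 kb gene pitch; ~2900 genes yield a ~3 Mb chromosome.

`derive_sisters` applies, in order: insertions/deletions (islands with
GC-biased composition, strain-specific IS transpositions into intergenic
sites), inversions between named repeat-pair midpoints, then SNPs. SNPs go
only into CDSs intact and co-linear in both strains, never in the first or
last codon, never in repeat/IS copies, at most one per codon; each
candidate substitution is classed by translating the whole mutated CDS and
comparing — a code path independent of the variants module — and rejection
sampling continues until each region's (count, non-synonymous fraction)
matches the spec exactly. Insertion sites keep 10 kb from each other and
6 kb from multi-copy features (relaxed progressively on small genomes) so
planted events remain individually resolvable; island edge bases are pinned
to differ from the flanking continuation so the unaligned segment length
equals the planted length exactly. All randomness flows from one integer
seed; fixtures are byte-reproducible.

What the fixtures do **not** emulate: real codon usage and amino-acid
composition (genes are uniform over sense codons), transition/transversion
bias, context-dependent mutation, IS copies that have diverged from their
family consensus, nested or partially deleted elements, assembly gaps and
errors, and gene-boundary annotation noise. Passing the planted-truth
tests therefore demonstrates the correctness of the algorithms under clean
annotations and literal sequence identity — not robustness to annotation
error or to repeat families at intermediate divergence, which real genomes
do contain.

## Problem sizes used in the packaged checks

The packaged end-to-end checks run the identity analysis at 3 Mb (one
pair), the classifier-vs-oracle comparison over 100 fixtures of ~40 kb with
100 coding SNPs each (10,000 SNPs), inversion ranking over 100 replicates
of 200 kb two-arm genomes, and orthology on 60-protein proteomes with 10%
decoy paralogs; these sizes exercise every code path at full scale for the
quantities that depend on scale (identity, anchor coverage) and at reduced
scale elsewhere, keeping the whole suite within a few minutes.

## Known limitations

* Pairwise only: no multi-genome alignment, no >2-track XMFA.
* Rearrangement handling is per-orientation chaining; interleaved
  multi-block shuffles (beyond clean inversions) produce chain splits, not
  a rearrangement-distance analysis.
* Aligning unrelated circular rotations requires pre-rotating one genome;
  the aligner does not heal blocks across the linearization junction.
* The Karlin–Altschul constants are fixed, not fitted per scoring system;
  e-values are comparable within this tool, not to other search engines.
* The symmetry score assumes exactly two replichore arms; genomes with
  multiple skew flips (recent large rearrangements) may have no confident
  origin call, and candidates are then ranked by the collinearity term
  alone when a reference is available.
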