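"""Synthetic sister-genome pairs with planted, recorded mutations.

The generator emulates the structure of a pair of recently diverged,
collinear bacterial chromosomes: a circular ancestor of non-overlapping
random-codon CDSs with rRNA-operon placeholders (including an inverted
pair), multi-copy IS elements, and an rdhA-like anchor gene next to a
Crp/Fnr-style regulator; sisters then differ by region-specific SNPs with
controlled non-synonymous fractions, strain-specific IS transpositions,
low-GC island insertions, repeat-mediated inversions, and deletions. Every
planted difference is recorded in a TruthTable in final coordinates of both
strains, and every planted coding SNP's synonymy class is verified at
planting time by whole-CDS translate-and-compare — a code path independent
of the variants module's codon-level classifier.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .genomeio import DomainHit, Feature, GenomeRecord, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in _STOPS]


@dataclass
class MutationSpec:
    """What separates the two sisters, and where.

    ``n_snps_by_region`` maps a region label to (count, target non-synonymous
    fraction); regions are ancestor-coordinate intervals in ``regions``.
    ``n_is_transpositions`` is (strain A, strain B) counts of strain-specific
    new IS copies. ``island_specs`` entries are (length bp, GC fraction,
    strain); ``inversions`` are ("tagX|tagY" repeat-pair label, strain);
    ``deletions`` are (region label, length bp, strain).
    """

    regions: dict = field(default_factory=dict)
    n_snps_by_region: dict = field(default_factory=dict)
    n_is_transpositions: tuple = (0, 0)
    island_specs: list = field(default_factory=list)
    inversions: list = field(default_factory=list)
    deletions: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for label, (count, frac) in self.n_snps_by_region.items():
            if count < 0:
                raise ValueError(f"region {label}: negative SNP count")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"region {label}: nonsyn fraction outside [0,1]")
            if label not in self.regions:
                raise ValueError(f"region {label} has no interval in spec.regions")
        for spec in self.island_specs:
            if not 0.0 < spec[1] < 1.0:
                raise ValueError("island gc_fraction must be in (0,1)")
        if any(n < 0 for n in self.n_is_transpositions):
            raise ValueError("negative transposition count")


@dataclass
class PlantedSNP:
    pos_ancestor: int
    posA: int
    posB: int
    baseA: str
    baseB: str
    klass: str
    locus_tag: str
    region: str


@dataclass
class PlantedEvent:
    kind: str  # IS_transposition | island | inversion | deletion
    label: str
    strain: str  # 'A' | 'B'
    intervalA: tuple  # final coordinates in strain A (may be zero-length)
    intervalB: tuple


@dataclass
class TruthTable:
    snps: list = field(default_factory=list)
    events: list = field(default_factory=list)
    ortholog_map: list = field(default_factory=list)
    regions_A: dict = field(default_factory=dict)  # region label -> strain-A interval

    def validate(self) -> None:
        for strain, key in (("A", "intervalA"), ("B", "intervalB")):
            ivals = sorted(getattr(e, key) for e in self.events
                           if getattr(e, key)[1] > getattr(e, key)[0])
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping event intervals in strain {strain}")


def _rand_dna(rng, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def _rand_gene(rng, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx) + "TAA"


def simulate_ancestor(n_genes: int = 60, n_rrna_operons: int = 3,
                      n_is_elements: int = 2, is_copy_counts: Optional[dict] = None,
                      seed: int = 0, gene_codons: tuple = (100, 500),
                      spacer_range: tuple = (60, 200),
                      genome_length: Optional[int] = None) -> GenomeRecord:
    """Build a circular ancestor genome; deterministic for a given seed.

    ``is_copy_counts`` maps IS family labels to multiplicities (default: the
    first family at nine copies — the extreme multi-copy case in these
    genomes — and two copies for each further family). One CDS is an
    rdhA-like anchor with an adjacent Crp/Fnr-style regulator CDS; rRNA
    operon placeholders are identical copies with one inserted inverted, so
    the genome always carries an inverted repeat pair.
    """
    if min(n_genes, n_rrna_operons, n_is_elements) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)

    if is_copy_counts is None:
        is_copy_counts = {f"IS{i + 1}": (9 if i == 0 else 2) for i in range(n_is_elements)}

    anchor_idx = n_genes // 2
    items: list[tuple] = [("gene", i) for i in range(n_genes)]
    specials: list[tuple] = [("rrn", i) for i in range(n_rrna_operons)]
    elements = {label: _rand_dna(rng, int(rng.integers(900, 1200))) for label in is_copy_counts}
    for label, count in is_copy_counts.items():
        specials += [("is", label, c) for c in range(count)]
    for sp in specials:
        items.insert(int(rng.integers(0, len(items) + 1)), sp)

    seq16 = _rand_dna(rng, 1500)
    seq23 = _rand_dna(rng, 2900)
    operon = seq16 + _rand_dna(rng, 100) + seq23

    parts: list[str] = []
    features: list[Feature] = []
    cur = 0

    def _emit(s: str):
        nonlocal cur
        parts.append(s)
        cur += len(s)

    for item in items:
        _emit(_rand_dna(rng, int(rng.integers(*spacer_range))))
        start = cur
        if item[0] == "gene":
            i = item[1]
            gene = _rand_gene(rng, int(rng.integers(*gene_codons)))
            strand = "+" if rng.random() < 0.5 else "-"
            if i == anchor_idx:
                tag, product, strand = "rdhA1", "reductive dehalogenase catalytic subunit (rdhA-like)", "+"
            elif i == anchor_idx + 1:
                tag, product, strand = "reg1", "Crp/Fnr transcriptional regulator (cNMP_binding; HTH_Crp_2)", "+"
            else:
                tag, product = f"gene{i:04d}", "hypothetical protein"
            _emit(gene if strand == "+" else revcomp(gene))
            features.append(Feature(tag, "CDS", start, cur, strand, product))
        elif item[0] == "rrn":
            i = item[1]
            inverted = i == n_rrna_operons - 1  # at least one inverted copy
            if not inverted:
                _emit(operon)
                features.append(Feature(f"rrn{i + 1}_16S", "rRNA", start, start + 1500, "+",
                                        "16S ribosomal RNA"))
                features.append(Feature(f"rrn{i + 1}_23S", "rRNA", start + 1600, start + len(operon),
                                        "+", "23S ribosomal RNA"))
            else:
                _emit(revcomp(operon))
                end = start + len(operon)
                features.append(Feature(f"rrn{i + 1}_16S", "rRNA", end - 1500, end, "-",
                                        "16S ribosomal RNA"))
                features.append(Feature(f"rrn{i + 1}_23S", "rRNA", start, start + 2900, "-",
                                        "23S ribosomal RNA"))
            features.append(Feature(f"rrn{i + 1}", "repeat_region", start, start + len(operon),
                                    "-" if inverted else "+", "rRNA operon"))
        else:
            _, label, c = item
            strand = "+" if rng.random() < 0.5 else "-"
            el = elements[label]
            _emit(el if strand == "+" else revcomp(el))
            features.append(Feature(f"{label}_c{c + 1}", "mobile_element", start, cur, strand,
                                    f"IS element {label} transposase"))
    _emit(_rand_dna(rng, int(rng.integers(*spacer_range))))

    if genome_length is not None:
        if cur > genome_length:
            raise ValueError(f"requested content ({cur} bp) exceeds genome length {genome_length}")
        _emit(_rand_dna(rng, genome_length - cur))

    return GenomeRecord(id=f"anc{seed}", seq="".join(parts), topology="circular",
                        features=features)


def element_sequences(genome: GenomeRecord) -> dict:
    """IS family label -> consensus (forward-orientation) sequence."""
    out = {}
    for f in genome.features:
        if f.ftype == "mobile_element":
            label = f.locus_tag.rsplit("_c", 1)[0]
            out.setdefault(label, genome.feature_seq(f))
    return out


def _oracle_class(cds_nt: str, offset: int, alt: str) -> str:
    """Whole-CDS translate-and-compare synonymy oracle (planting-time path)."""
    mutant = cds_nt[:offset] + alt + cds_nt[offset + 1:]
    aa0 = str(Seq(cds_nt).translate(table=11))
    aa1 = str(Seq(mutant).translate(table=11))
    if aa0 == aa1:
        return "synonymous"
    diff = [(x, y) for x, y in zip(aa0, aa1) if x != y]
    if any(y == "*" for _, y in diff):
        return "nonsense"
    return "nonsynonymous"


class _CoordMap:
    """Ancestor -> strain coordinate map: indels first, then inversions."""

    def __init__(self, segments: list[tuple[int, int, int]], length: int):
        # segments: (anc_start, anc_end, new_start), sorted by anc_start
        self.segments = segments
        self.starts = [s[0] for s in segments]
        self.inversions: list[tuple[int, int]] = []
        self.length = length

    def __call__(self, pos: int) -> Optional[int]:
        i = bisect_right(self.starts, pos) - 1
        if i < 0:
            return None
        s, e, ns = self.segments[i]
        if not s <= pos < e:
            return None
        p = ns + (pos - s)
        for a, b in self.inversions:
            if a <= p < b:
                p = a + b - 1 - p
        return p

    def interval(self, start: int, end: int) -> Optional[tuple[int, int]]:
        a, b = self(start), self(end - 1)
        if a is None or b is None:
            return None
        lo, hi = min(a, b), max(a, b)
        if hi - lo != end - 1 - start:
            return None  # split by an event
        return lo, hi + 1


def _apply_indels(ancestor: GenomeRecord, insertions, deletions, tag_prefix: str):
    """Apply insertions/deletions; returns (seq, features, coord_map, new_feats).

    insertions: list of (anc_pos, seq, label, kind, strand); deletions:
    (anc_start, anc_end, label). Features overlapping a deletion are dropped.
    """
    events = sorted(
        [(pos, "ins", s, label, kind, strand) for pos, s, label, kind, strand in insertions]
        + [(s, "del", e, label, None, None) for s, e, label in deletions]
    )
    parts, segments = [], []
    cur = out = 0
    inserted_feats = []
    event_intervals = []  # (kind, label, new_start, new_end)
    for ev in events:
        if ev[1] == "ins":
            pos, _, s, label, kind, strand = ev
            if pos > cur:
                parts.append(ancestor.seq[cur:pos])
                segments.append((cur, pos, out))
                out += pos - cur
                cur = pos
            parts.append(s)
            event_intervals.append((kind, label, out, out + len(s)))
            if kind == "IS_transposition":
                fam = label.split(":")[0]
                inserted_feats.append(Feature(f"{tag_prefix}{label.replace(':', '_')}",
                                              "mobile_element", out, out + len(s), strand,
                                              f"IS element {fam} transposase"))
            out += len(s)
        else:
            s, _, e, label, _, _ = ev
            if s > cur:
                parts.append(ancestor.seq[cur:s])
                segments.append((cur, s, out))
                out += s - cur
            event_intervals.append(("deletion", label, out, out))
            cur = e
    if cur < len(ancestor.seq):
        parts.append(ancestor.seq[cur:])
        segments.append((cur, len(ancestor.seq), out))
        out += len(ancestor.seq) - cur
    cmap = _CoordMap(segments, out)
    features = []
    for f in ancestor.features:
        ival = cmap.interval(f.start, f.end)
        if ival is None:
            continue
        features.append(Feature(tag_prefix + f.locus_tag, f.ftype, ival[0], ival[1],
                                f.strand, f.product, f.translation, f.pseudo, f.codon_excluded))
    return "".join(parts), features + inserted_feats, cmap, event_intervals


def _intergenic_sites(genome: GenomeRecord, rng, n: int, margin: int = 20,
                      min_sep: int = 10_000, repeat_margin: int = 6_000,
                      forbidden: list = ()) -> list[int]:
    """Choose n well-separated intergenic insertion points.

    Sites keep ``repeat_margin`` away from multi-copy features (IS elements,
    rRNA operons) so each planted insertion sits in uniquely alignable
    flanking sequence, and ``min_sep`` apart from each other so planted
    events do not coalesce into one unalignable region. Both stand-offs are
    relaxed progressively on small genomes where they cannot all hold.
    """
    for shrink in (1.0, 0.5, 0.25, 0.1, 0.0):
        rm = int(repeat_margin * shrink)
        ms = max(100, int(min_sep * shrink))
        occupied = []
        for f in genome.features:
            m = rm if f.ftype in ("mobile_element", "repeat_region", "rRNA") else 0
            occupied.append((f.start - m, f.end + m))
        occupied.sort()
        free = []
        pos = 0
        for s, e in occupied:
            if s - pos > 2 * margin:
                free.append((pos + margin, s - margin))
            pos = max(pos, e)
        if len(genome) - pos > 2 * margin:
            free.append((pos + margin, len(genome) - margin))
        free = [(s, e) for s, e in free
                if not any(fs < e and s < fe for fs, fe in forbidden)]
        if not free:
            continue
        sites: list[int] = []
        attempts = 0
        while len(sites) < n and attempts <= 200 * (n + 1):
            attempts += 1
            s, e = free[int(rng.integers(0, len(free)))]
            p = int(rng.integers(s, e))
            if all(abs(p - q) >= ms for q in sites):
                sites.append(p)
        if len(sites) == n:
            return sites
    raise ValueError("could not place all insertion events in intergenic space")


def derive_sisters(ancestor: GenomeRecord, spec: MutationSpec):
    """Derive two sisters from one ancestor per the mutation spec.

    Strain A receives islands/deletions/transpositions labeled 'A'; all SNPs
    are applied to strain B (so genome A carries the ancestral allele), as do
    B-labeled structural events. Realized per-region SNP counts and
    non-synonymous fractions equal the spec exactly, by rejection sampling
    against the planting-time whole-CDS translate-and-compare oracle.
    Returns (strainA, strainB, TruthTable).
    """
    rng = np.random.default_rng(spec.seed)
    for label, (s, e) in spec.regions.items():
        if not 0 <= s < e <= len(ancestor):
            raise ValueError(f"region {label} outside ancestor")

    elements = element_sequences(ancestor)
    region_ivals = list(spec.regions.values())

    ins = {"A": [], "B": []}
    dels = {"A": [], "B": []}
    # deletions (ancestor coordinates; cut from the region start)
    for label, length, strain in spec.deletions:
        s, e = spec.regions[label]
        if length > e - s:
            raise ValueError(f"deletion longer than region {label}")
        dels[strain].append((s, s + length, label))
    # islands and IS transpositions need intergenic sites away from SNP regions
    n_sites = {"A": 0, "B": 0}
    for _l, _gc, strain in spec.island_specs:
        n_sites[strain] += 1
    n_sites["A"] += spec.n_is_transpositions[0]
    n_sites["B"] += spec.n_is_transpositions[1]
    sites = {s: _intergenic_sites(ancestor, rng, n_sites[s], forbidden=region_ivals)
             if n_sites[s] else [] for s in "AB"}
    for i, (length, gc, strain) in enumerate(spec.island_specs):
        site = sites[strain].pop()
        island = _rand_dna(rng, length, gc=gc)
        # pin the island edges: first/last base must differ from the base the
        # other strain continues with, so anchors stop exactly at the island
        # boundary and the unaligned segment length equals the planted length
        for idx, clash in ((0, ancestor.seq[site]), (length - 1, ancestor.seq[site - 1])):
            if island[idx] == clash:
                repl = "ACGT"[("ACGT".index(clash) + 1 + int(rng.integers(0, 3))) % 4]
                island = island[:idx] + repl + island[idx + 1:] if idx else repl + island[1:]
        ins[strain].append((site, island, f"island{i + 1}", "island", "+"))
    fams = sorted(elements)
    for strain, n_tr in zip("AB", spec.n_is_transpositions):
        for i in range(n_tr):
            fam = fams[int(rng.integers(0, len(fams)))]
            strand = "+" if rng.random() < 0.5 else "-"
            el = elements[fam] if strand == "+" else revcomp(elements[fam])
            ins[strain].append((sites[strain].pop(), el, f"{fam}:tx{strain}{i + 1}",
                                "IS_transposition", strand))

    seqA, featsA, mapA, eventsA = _apply_indels(ancestor, ins["A"], dels["A"], "A_")
    seqB, featsB, mapB, eventsB = _apply_indels(ancestor, ins["B"], dels["B"], "B_")
    genomeA = GenomeRecord(f"{ancestor.id}_A", seqA, "circular", featsA)
    genomeB = GenomeRecord(f"{ancestor.id}_B", seqB, "circular", featsB)

    truth = TruthTable()
    for kind, label, s, e in eventsA:
        truth.events.append(PlantedEvent(kind, label, "A", (s, e), _map_point(mapB, mapA, s, e)))
    for kind, label, s, e in eventsB:
        truth.events.append(PlantedEvent(kind, label, "B", _map_point(mapA, mapB, s, e), (s, e)))

    # inversions between planted repeat-pair midpoints
    from .skew import apply_inversion

    for pair_label, strain in spec.inversions:
        tag1, tag2 = pair_label.split("|")
        genome = genomeA if strain == "A" else genomeB
        prefix = "A_" if strain == "A" else "B_"
        f1, f2 = genome.get(prefix + tag1), genome.get(prefix + tag2)
        m1 = (f1.start + f1.end) // 2
        m2 = (f2.start + f2.end) // 2
        i, j = min(m1, m2), max(m1, m2)
        genome = apply_inversion(genome, i, j)
        if strain == "A":
            genomeA = genome
            mapA.inversions.append((i, j))
            truth.events.append(PlantedEvent("inversion", pair_label, "A", (i, j), (0, 0)))
        else:
            genomeB = genome
            mapB.inversions.append((i, j))
            truth.events.append(PlantedEvent("inversion", pair_label, "B", (0, 0), (i, j)))

    # --- SNP planting ---------------------------------------------------
    def _clean_in_both(f: Feature) -> bool:
        ia = mapA.interval(f.start, f.end)
        ib = mapB.interval(f.start, f.end)
        if ia is None or ib is None:
            return False
        for (s, e) in mapA.inversions:
            if ia[0] < e and s < ia[1]:
                return False
        for (s, e) in mapB.inversions:
            if ib[0] < e and s < ib[1]:
                return False
        return True

    seqB_mut = bytearray(genomeB.seq, "ascii")
    used_positions: set[int] = set()
    used_codons: set[tuple[str, int]] = set()

    for label, (count, frac) in spec.n_snps_by_region.items():
        rs, re = spec.regions[label]
        n_nonsyn = int(round(count * frac))
        cands = [f for f in ancestor.cds(include_excluded=False)
                 if rs <= f.start and f.end <= re and _clean_in_both(f)]
        if count and not cands:
            raise ValueError(f"region {label} has no usable CDS for SNP planting")
        weights = np.array([len(f) for f in cands], dtype=float)
        need = {"nonsynonymous": n_nonsyn, "synonymous": count - n_nonsyn}
        if count and need["synonymous"] and not cands:
            raise ValueError(f"infeasible spec for region {label}")
        attempts = 0
        while need["nonsynonymous"] or need["synonymous"]:
            attempts += 1
            if attempts > 2000 * (count + 1):
                raise ValueError(f"could not realize SNP spec for region {label}")
            f = cands[int(rng.choice(len(cands), p=weights / weights.sum()))]
            ncod = len(f) // 3
            if ncod < 4:
                continue
            ci = int(rng.integers(1, ncod - 1))
            cp = int(rng.integers(0, 3))
            offset = ci * 3 + cp
            pos = f.start + offset if f.strand == "+" else f.end - 1 - offset
            if pos in used_positions or (f.locus_tag, ci) in used_codons:
                continue
            cds_nt = ancestor.feature_seq(f)
            ref_cds_base = cds_nt[offset]
            alt_cds_base = "ACGT"[int(rng.integers(0, 4))]
            if alt_cds_base == ref_cds_base:
                continue
            klass = _oracle_class(cds_nt, offset, alt_cds_base)
            if klass not in need or need[klass] == 0:
                continue
            need[klass] -= 1
            used_positions.add(pos)
            used_codons.add((f.locus_tag, ci))
            baseA = ancestor.seq[pos]
            baseB = alt_cds_base if f.strand == "+" else alt_cds_base.translate(
                str.maketrans("ACGT", "TGCA"))
            posA, posB = mapA(pos), mapB(pos)
            seqB_mut[posB] = ord(baseB)
            truth.snps.append(PlantedSNP(pos, posA, posB, baseA, baseB, klass,
                                         f.locus_tag, label))

    genomeB = GenomeRecord(genomeB.id, seqB_mut.decode(), "circular", genomeB.features)

    truth.ortholog_map = [
        ("A_" + f.locus_tag, "B_" + f.locus_tag) for f in ancestor.features
        if f.ftype == "CDS" and _has_tag(genomeA, "A_" + f.locus_tag)
        and _has_tag(genomeB, "B_" + f.locus_tag)
    ]
    truth.regions_A = {
        label: mapA.interval(*spec.regions[label]) or (mapA(spec.regions[label][0]) or 0,) * 2
        for label in spec.regions
    }
    truth.snps.sort(key=lambda s: s.posA)
    truth.validate()
    return genomeA, genomeB, truth


def _map_point(other_map: _CoordMap, own_map: _CoordMap, s: int, e: int) -> tuple[int, int]:
    """Zero-length interval in the other strain at the event's flank."""
    # find ancestor coordinate whose own-strain image is s (segment boundary)
    for anc_s, anc_e, ns in own_map.segments:
        if ns >= s:
            p = other_map(anc_s)
            return (p, p) if p is not None else (0, 0)
    return (other_map.length, other_map.length)


def _has_tag(genome: GenomeRecord, tag: str) -> bool:
    return any(f.locus_tag == tag for f in genome.features)


def domain_hits_for(genome: GenomeRecord, evalue: float = 1e-20) -> list[DomainHit]:
    """Planted domain labels: read from product annotations of regulator CDSs.

    Products formatted "... (Dom1; Dom2)" yield one DomainHit per listed
    domain — the fixture analog of a pfam_scan run over the proteome.
    """
    hits = []
    for f in genome.features:
        if f.ftype != "CDS" or "(" not in f.product or not f.product.endswith(")"):
            continue
        inner = f.product[f.product.rindex("(") + 1:-1]
        names = [d.strip() for d in inner.split(";") if d.strip()]
        aa_len = max(1, len(f) // 3 - 1)
        for i, name in enumerate(names):
            s = min(i * 10, aa_len - 1)
            hits.append(DomainHit(f.locus_tag, name, evalue, s, min(s + 50, aa_len)))
    return hits


def write_fixture(pair, truth: TruthTable, outdir: str, spec: Optional[MutationSpec] = None,
                  overwrite: bool = False) -> None:
    """Write FASTA+GFF3 per strain, truth TSVs, and a config echo."""
    import yaml

    from .genomeio import write_fasta, write_gff3

    if os.path.isdir(outdir) and os.listdir(outdir) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (pass overwrite=True)")
    os.makedirs(outdir, exist_ok=True)
    genomeA, genomeB = pair
    for g, name in ((genomeA, "A"), (genomeB, "B")):
        write_fasta(g, os.path.join(outdir, f"strain{name}.fasta"))
        write_gff3(g, os.path.join(outdir, f"strain{name}.gff3"))
    with open(os.path.join(outdir, "truth_snps.tsv"), "w") as fh:
        fh.write("pos_ancestor\tposA\tposB\tbaseA\tbaseB\tklass\tlocus_tag\tregion\n")
        for s in truth.snps:
            fh.write(f"{s.pos_ancestor}\t{s.posA}\t{s.posB}\t{s.baseA}\t{s.baseB}\t"
                     f"{s.klass}\t{s.locus_tag}\t{s.region}\n")
    with open(os.path.join(outdir, "truth_events.tsv"), "w") as fh:
        fh.write("kind\tlabel\tstrain\tstartA\tendA\tstartB\tendB\n")
        for e in truth.events:
            fh.write(f"{e.kind}\t{e.label}\t{e.strain}\t{e.intervalA[0]}\t{e.intervalA[1]}\t"
                     f"{e.intervalB[0]}\t{e.intervalB[1]}\n")
    with open(os.path.join(outdir, "ortholog_map.tsv"), "w") as fh:
        fh.write("locusA\tlocusB\n")
        for a, b in truth.ortholog_map:
            fh.write(f"{a}\t{b}\n")
    if spec is not None:
        cfg = asdict(spec)
        cfg["n_snps_by_region"] = {k: list(v) for k, v in cfg["n_snps_by_region"].items()}
        with open(os.path.join(outdir, "config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def load_fixture(outdir: str):
    """Re-load a written fixture's two genomes via genomeio."""
    from .genomeio import read_gff3

    a = read_gff3(os.path.join(outdir, "strainA.gff3"), os.path.join(outdir, "strainA.fasta"))
    b = read_gff3(os.path.join(outdir, "strainB.gff3"), os.path.join(outdir, "strainB.fasta"))
    return a, b
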