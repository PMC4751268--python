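"""Readers/writers for external formats and the shared genome data model.

All internal coordinates are 0-based half-open on the forward strand;
strandedness is carried by a flag, never by storing reverse-complemented
feature sequence. GenBank and GFF3 coordinates (1-based inclusive) are
converted on the way in and restored on the way out.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "repeat_region", "mobile_element", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Feature:
    """A typed, stranded annotation on a genome.

    ``codon_excluded`` marks features whose compound (join) location or
    nonzero phase makes codon-level analysis unsafe; they still count for
    gene-order neighborhood windows. ``broken`` marks features split by a
    rearrangement breakpoint.
    """

    locus_tag: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    translation: Optional[str] = None
    pseudo: bool = False
    codon_excluded: bool = False
    broken: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"feature {self.locus_tag}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.locus_tag}: bad strand {self.strand!r}")
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"feature {self.locus_tag}: unknown ftype {self.ftype!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A circular or linear genome sequence with ordered features."""

    id: str
    seq: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise ValueError("genome id must be nonempty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.sort_features()
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"feature {f.locus_tag} [{f.start},{f.end}) beyond sequence end {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.locus_tag))

    def feature_seq(self, feat: Feature) -> str:
        """Forward-extracted span, reverse-complemented for '-' features."""
        s = self.seq[feat.start:feat.end]
        return revcomp(s) if feat.strand == "-" else s

    def cds(self, include_excluded: bool = True) -> list[Feature]:
        return [
            f for f in self.features
            if f.ftype == "CDS" and (include_excluded or not (f.codon_excluded or f.pseudo))
        ]

    def get(self, locus_tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)


@dataclass
class DomainHit:
    """One protein-domain match in protein coordinates (0-based half-open)."""

    locus_tag: str
    domain_name: str
    evalue: float
    env_start: int
    env_end: int

    def __post_init__(self):
        if self.evalue <= 0 and self.evalue != 0.0:
            raise ValueError("evalue must be positive")


class Hit(NamedTuple):
    """One row of 12-column tabular protein-search output."""

    query: str
    subject: str
    pct_id: float
    length: int
    evalue: float
    bitscore: float


def _clean_seq(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = sum(1 for c in seq if c not in "ACGTN")
    if bad:
        log.warning("%s: %d non-ACGTN characters mapped to N", record_id, bad)
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def read_fasta(path: str, topology: str = "linear") -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords with empty feature lists."""
    records = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, seq=_clean_seq(str(rec.seq), rec.id), topology=topology))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path: str, width: int = 70) -> None:
    if isinstance(records, GenomeRecord):
        records = [records]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


_GENBANK_TYPE_MAP = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "repeat_region": "repeat_region",
    "mobile_element": "mobile_element",
    "misc_feature": "other",
    "ncRNA": "other",
    "tmRNA": "other",
}


def _synth_tag(ftype: str, start: int, end: int) -> str:
    return f"{ftype}_{start}_{end}"


def read_genbank(path: str) -> GenomeRecord:
    """Read a single-locus GenBank flat file into a GenomeRecord."""
    try:
        rec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: missing ORIGIN sequence")
    except Exception as exc:  # UndefinedSequenceError
        raise FormatError(f"{path}: missing ORIGIN sequence ({exc})") from exc
    topology = rec.annotations.get("topology", "linear")
    features = []
    for f in rec.features:
        ftype = _GENBANK_TYPE_MAP.get(f.type)
        if ftype is None:
            continue
        start = int(f.location.start)
        end = int(f.location.end)
        if end > len(seq):
            raise FormatError(f"{path}: feature at {start}..{end} beyond sequence end")
        compound = len(f.location.parts) > 1
        quals = f.qualifiers
        tag = quals.get("locus_tag", [None])[0] or _synth_tag(ftype, start, end)
        feat = Feature(
            locus_tag=tag,
            ftype=ftype,
            start=start,
            end=end,
            strand="-" if f.location.strand == -1 else "+",
            product=quals.get("product", [""])[0],
            translation=quals.get("translation", [None])[0],
            pseudo="pseudo" in quals or "pseudogene" in quals,
            codon_excluded=compound,
        )
        if compound:
            log.info("%s: compound location for %s; excluded from codon analyses", path, tag)
        features.append(feat)
    return GenomeRecord(id=rec.id or rec.name, seq=_clean_seq(seq, rec.id), topology=topology, features=features)


_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "repeat_region": "repeat_region",
    "mobile_genetic_element": "mobile_element",
    "mobile_element": "mobile_element",
}


def read_gff3(gff_path: str, fasta_path: str) -> GenomeRecord:
    """Read a GFF3 annotation plus its FASTA sequence into a GenomeRecord.

    GFF 1-based inclusive intervals are converted to 0-based half-open.
    CDS rows with nonzero phase are flagged and excluded from codon analyses.
    """
    import gffutils

    genome = read_fasta(fasta_path)[0]
    db = gffutils.create_db(
        gff_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features = []
    topology = genome.topology
    for f in db.all_features():
        if f.featuretype == "region":
            if f.attributes.get("Is_circular", ["false"])[0].lower() == "true":
                topology = "circular"
            continue
        ftype = _GFF_TYPE_MAP.get(f.featuretype)
        if ftype is None:
            continue
        start, end = f.start - 1, f.end
        tag = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [None])[0]
        if tag is None:
            tag = _synth_tag(ftype, start, end)
            log.warning("%s: feature %d..%d lacks locus_tag; synthesized %s", gff_path, f.start, f.end, tag)
        phased = ftype == "CDS" and f.frame not in (".", "0", 0, None)
        feat = Feature(
            locus_tag=tag,
            ftype=ftype,
            start=start,
            end=end,
            strand="-" if f.strand == "-" else "+",
            product=(f.attributes.get("product") or [""])[0],
            pseudo="pseudo" in f.attributes,
            codon_excluded=phased,
        )
        features.append(feat)
    return GenomeRecord(id=genome.id, seq=genome.seq, topology=topology, features=features)


def write_gff3(genome: GenomeRecord, path: str, source: str = "sisterscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        circ = "true" if genome.topology == "circular" else "false"
        fh.write(
            f"{genome.id}\t{source}\tregion\t1\t{len(genome)}\t.\t+\t.\t"
            f"ID=region_{genome.id};Is_circular={circ}\n"
        )
        rev = {v: k for k, v in _GFF_TYPE_MAP.items()}
        for f in genome.features:
            gtype = rev.get(f.ftype, "misc_feature" if f.ftype == "other" else f.ftype)
            attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.pseudo:
                attrs.append("pseudo=true")
            fh.write(
                f"{genome.id}\t{source}\t{gtype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                + ";".join(attrs) + "\n"
            )


def read_xmfa(path: str):
    """Read a pairwise XMFA file into AlignmentBlocks.

    Blocks must have exactly two tracks (pairwise alignments only); the first
    track is genome A, the second genome B. Reverse-strand B segments are
    stored with a reverse orientation flag and coordinates on the forward
    strand.
    """
    from .align import block_from_aligned  # deferred: align imports genomeio types

    blocks = []
    for aln in AlignIO.parse(path, "mauve"):
        recs = list(aln)
        if len(recs) != 2:
            raise FormatError(f"{path}: XMFA block with {len(recs)} tracks; pairwise required")
        a, b = recs
        if a.annotations["strand"] == -1:
            raise FormatError(f"{path}: first (reference) track on reverse strand unsupported")
        orientation = "reverse" if b.annotations["strand"] == -1 else "forward"
        blocks.append(
            block_from_aligned(
                str(a.seq).upper(), str(b.seq).upper(),
                a.annotations["start"], b.annotations["start"], orientation,
            )
        )
    return blocks


def write_xmfa(blocks, seqA: str, seqB: str, path: str, nameA: str = "A", nameB: str = "B") -> None:
    """Write pairwise AlignmentBlocks as XMFA (1-based inclusive headers)."""
    with open(path, "w") as fh:
        fh.write("#FormatVersion Mauve1\n")
        for blk in blocks:
            alnA, alnB = blk.aligned_strings(seqA, seqB)
            sA, eA = blk.intervalA
            sB, eB = blk.intervalB
            strandB = "-" if blk.orientation == "reverse" else "+"
            fh.write(f"> 1:{sA + 1}-{eA} + {nameA}\n")
            for i in range(0, len(alnA), 80):
                fh.write(alnA[i:i + 80] + "\n")
            fh.write(f"> 2:{sB + 1}-{eB} {strandB} {nameB}\n")
            for i in range(0, len(alnB), 80):
                fh.write(alnB[i:i + 80] + "\n")
            fh.write("=\n")


def read_search_tab(path: str) -> list[Hit]:
    """Read 12-column tabular protein-search output ("outfmt 6" dialect)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, found {len(cols)}")
            try:
                hits.append(
                    Hit(
                        query=cols[0], subject=cols[1],
                        pct_id=float(cols[2]), length=int(cols[3]),
                        evalue=float(cols[10]), bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_search_tab(hits, path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.pct_id:.1f}\t{h.length}\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )


def read_domtab(path: str) -> list[DomainHit]:
    """Read pfam_scan-style whitespace-delimited domain hits.

    Column layout (pfam_scan.pl): seq_id, aln start/end, envelope start/end,
    hmm acc, hmm name, type, hmm start/end/length, bit score, E-value, ...
    Envelope coordinates are 1-based inclusive and converted to 0-based
    half-open.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 13:
                raise FormatError(f"{path}:{lineno}: expected >=13 columns, found {len(cols)}")
            try:
                out.append(
                    DomainHit(
                        locus_tag=cols[0],
                        domain_name=cols[6],
                        evalue=float(cols[12]),
                        env_start=int(cols[3]) - 1,
                        env_end=int(cols[4]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_domtab(hits, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# <seq id> <aln st> <aln en> <env st> <env en> <hmm acc> <hmm name> "
                 "<type> <hmm st> <hmm en> <hmm ln> <bit score> <E-value>\n")
        for h in hits:
            fh.write(
                f"{h.locus_tag} {h.env_start + 1} {h.env_end} {h.env_start + 1} {h.env_end} "
                f"PF00000.0 {h.domain_name} Domain 1 {h.env_end - h.env_start} "
                f"{h.env_end - h.env_start} 50.0 {h.evalue:g}\n"
            )


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate a CDS (bacterial table 11), alternative starts as M.

    The trailing stop codon, when present, is dropped. Alternative start
    codons (GTG, TTG) are rendered as M at position 0 only.
    """
    if len(nt) % 3:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if aa and nt[:3] in ("ATG", "GTG", "TTG"):
        aa = "M" + aa[1:]
    return aa
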