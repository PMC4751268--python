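"""Maximal direct/inverted repeat discovery, IS copy-number counting, and
flanking-repeat detection.

Repeats are found by exact k-mer seeding (k=16), diagonal-run merging, and
ungapped x-drop extension; IS copies are counted by seeding candidate loci
and verifying each with a semi-global edit-distance alignment of the element
against the locus, accepting greedily by identity under a non-overlap
constraint. Copies are counted on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import _kmer_hashes, encode
from .genomeio import GenomeRecord, revcomp


@dataclass
class RepeatPair:
    intervalA: tuple[int, int]
    intervalB: tuple[int, int]
    orientation: str  # 'direct' | 'inverted'
    length: int
    pct_id: float


@dataclass
class Copy:
    start: int
    end: int
    strand: str
    pct_id: float
    coverage: float


@dataclass
class CopyNumberReport:
    element_id: str
    genome_id: str
    copies: list[Copy] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.copies)


def _seed_pairs(seqX: str, seqY: str, k: int = 16, maxocc: int = 100,
                self_compare: bool = False):
    """(px, py) arrays of exact k-mer matches between two sequences.

    K-mers occurring more than ``maxocc`` times in Y are skipped (tandem
    noise control). With ``self_compare`` only px < py pairs are kept.
    """
    hX, vX = _kmer_hashes(encode(seqX), k)
    hY, vY = _kmer_hashes(encode(seqY), k)
    posY = np.flatnonzero(vY)
    valsY = hY[posY]
    order = np.argsort(valsY, kind="stable")
    valsY, posY = valsY[order], posY[order]
    posX = np.flatnonzero(vX)
    valsX = hX[posX]
    lo = np.searchsorted(valsY, valsX, side="left")
    hi = np.searchsorted(valsY, valsX, side="right")
    counts = hi - lo
    keep = (counts > (1 if self_compare else 0)) & (counts <= maxocc)
    if self_compare:
        keep &= counts > 1
    px_parts, py_parts = [], []
    for x, l, h in zip(posX[keep], lo[keep], hi[keep]):
        ys = posY[l:h]
        px_parts.append(np.full(len(ys), x, dtype=np.int64))
        py_parts.append(ys.astype(np.int64))
    if not px_parts:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    px = np.concatenate(px_parts)
    py = np.concatenate(py_parts)
    if self_compare:
        m = px < py
        px, py = px[m], py[m]
    return px, py


def _merge_diag_seeds(px, py, k: int, merge_gap: int):
    """Group seeds by diagonal and merge those within ``merge_gap`` into
    candidate segments [(x0, y0, length), ...]."""
    if len(px) == 0:
        return []
    diag = py - px
    order = np.lexsort((px, diag))
    px, py, diag = px[order], py[order], diag[order]
    segs = []
    x0 = xe = px[0]
    d0 = diag[0]
    for x, d in zip(px[1:], diag[1:]):
        if d == d0 and x - xe <= merge_gap:
            xe = x
        else:
            segs.append((int(x0), int(x0 + d0), int(xe - x0) + k))
            x0 = xe = x
            d0 = d
    segs.append((int(x0), int(x0 + d0), int(xe - x0) + k))
    return segs


def _xdrop_extend(seqX: str, seqY: str, x0: int, y0: int, length: int,
                  xdrop: int = 12, match: int = 1, mismatch: int = -2):
    """Ungapped x-drop extension of an exact core in both directions.

    Returns (x_start, y_start, length, n_matches) of the best extended span.
    """
    # left
    best = score = 0
    bl = 0
    i, j, steps = x0 - 1, y0 - 1, 0
    while i >= 0 and j >= 0:
        steps += 1
        score += match if seqX[i] == seqY[j] and seqX[i] != "N" else mismatch
        if score > best:
            best, bl = score, steps
        if best - score > xdrop:
            break
        i -= 1; j -= 1
    left_matches = sum(1 for t in range(1, bl + 1) if seqX[x0 - t] == seqY[y0 - t])
    # right
    best = score = 0
    br = 0
    i, j, steps = x0 + length, y0 + length, 0
    n = min(len(seqX) - (x0 + length), len(seqY) - (y0 + length))
    while steps < n:
        score += match if seqX[i] == seqY[j] and seqX[i] != "N" else mismatch
        steps += 1
        if score > best:
            best, br = score, steps
        if best - score > xdrop:
            break
        i += 1; j += 1
    right_matches = sum(1 for t in range(br) if seqX[x0 + length + t] == seqY[y0 + length + t])
    xs, ys = x0 - bl, y0 - bl
    total = bl + length + br
    matches = left_matches + length + right_matches
    return xs, ys, total, matches


def _merge_pairs_on_diag(cands):
    """Union overlapping candidate spans sharing a diagonal."""
    cands = sorted(cands)
    out = []
    for xs, ys, ln, mt in cands:
        if out:
            pxs, pys, pln, pmt = out[-1]
            if ys - xs == pys - pxs and xs <= pxs + pln:
                new_end = max(pxs + pln, xs + ln)
                # matches approximated by the better-covered union
                out[-1] = (pxs, pys, new_end - pxs, max(pmt, mt + (xs - pxs)))
                continue
        out.append((xs, ys, ln, mt))
    return out


def maximal_repeats(genome, min_len: int = 24, min_id: float = 0.9,
                    k: int = 16, maxocc: int = 100) -> list[RepeatPair]:
    """Direct and inverted repeat pairs >= min_len at >= min_id identity.

    Deterministic seed-and-extend: exact 16-mer seeds in both orientations,
    diagonal merging, ungapped x-drop extension, and per-diagonal union of
    overlapping reported pairs. Pairs whose two intervals overlap (tandem
    cores, palindrome centers) are suppressed.
    """
    if min_len < 24:
        raise ValueError("min_len must be >= 24")
    seq = genome.seq if isinstance(genome, GenomeRecord) else genome
    L = len(seq)
    out: list[RepeatPair] = []

    # direct
    px, py = _seed_pairs(seq, seq, k=k, maxocc=maxocc, self_compare=True)
    cands = []
    for x0, y0, ln in _merge_diag_seeds(px, py, k, merge_gap=2 * k):
        cands.append(_xdrop_extend(seq, seq, x0, y0, ln))
    for xs, ys, ln, mt in _merge_pairs_on_diag(cands):
        pid = mt / ln
        if ln >= min_len and pid >= min_id and xs + ln <= ys:
            out.append(RepeatPair((xs, xs + ln), (ys, ys + ln), "direct", ln, 100 * pid))

    # inverted: genome vs its reverse complement
    rc = revcomp(seq)
    px, py = _seed_pairs(seq, rc, k=k, maxocc=maxocc)
    cands = []
    for x0, y0, ln in _merge_diag_seeds(px, py, k, merge_gap=2 * k):
        cands.append(_xdrop_extend(seq, rc, x0, y0, ln))
    seen = set()
    for xs, ys, ln, mt in _merge_pairs_on_diag(cands):
        pid = mt / ln
        ys_f = L - (ys + ln)  # forward-strand start of the rc-matched span
        a, b = (xs, ys_f) if xs <= ys_f else (ys_f, xs)
        if ln >= min_len and pid >= min_id and a + ln <= b and (a, b, ln) not in seen:
            seen.add((a, b, ln))
            out.append(RepeatPair((a, a + ln), (b, b + ln), "inverted", ln, 100 * pid))

    out.sort(key=lambda r: (r.intervalA, r.intervalB))
    return out


def _cigar_stats(cigar: str):
    matches = mism = ins = dele = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch == "=":
                matches += n
            elif ch == "X":
                mism += n
            elif ch == "I":
                ins += n
            elif ch == "D":
                dele += n
    return matches, mism, ins, dele


def count_element_copies(element_seq: str, genome, min_id: float = 0.95,
                         min_cov: float = 0.90, k: int = 16) -> CopyNumberReport:
    """Count non-overlapping placements of an element in one genome.

    Candidate loci are seeded by exact k-mers on both strands; each is
    verified by semi-global alignment of the full element against the locus
    (edlib), giving identity (matches / element length) and coverage
    ((matches + mismatches) / element length). Candidates are accepted
    greedily by identity under a non-overlap constraint.
    """
    g = genome if isinstance(genome, GenomeRecord) else GenomeRecord("g", genome)
    if len(element_seq) < 100:
        raise ValueError("element length must be >= 100")
    if len(element_seq) > len(g):
        raise ValueError("element longer than genome")
    el_len = len(element_seq)
    pad = max(50, el_len // 10)
    candidates = []
    for strand, el in (("+", element_seq), ("-", revcomp(element_seq))):
        px, py = _seed_pairs(el, g.seq, k=k, maxocc=500)
        if len(px) == 0:
            continue
        starts = np.sort(py - px)  # implied element start in the genome
        # cluster implied starts into loci
        cluster_lo = starts[0]
        prev = starts[0]
        loci = []
        for s in starts[1:]:
            if s - prev > el_len // 2:
                loci.append((cluster_lo, prev))
                cluster_lo = s
            prev = s
        loci.append((cluster_lo, prev))
        for lo, hi in loci:
            ws = max(0, int(lo) - pad)
            we = min(len(g), int(hi) + el_len + pad)
            res = edlib.align(el, g.seq[ws:we], mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            m, x, i, d = _cigar_stats(res["cigar"])
            pid = m / el_len
            cov = (m + x) / el_len
            s, e = res["locations"][0]
            candidates.append(Copy(ws + s, ws + e + 1, strand, 100 * pid, cov))
    candidates.sort(key=lambda c: (-c.pct_id, c.start))
    accepted: list[Copy] = []
    for c in candidates:
        if c.pct_id < 100 * min_id or c.coverage < min_cov:
            continue
        if any(c.start < a.end and a.start < c.end for a in accepted):
            continue
        accepted.append(c)
    accepted.sort(key=lambda c: c.start)
    return CopyNumberReport("element", g.id, accepted)


def copy_number_table(elements: dict, genomes: list):
    """Per-element x per-genome copy counts as a pandas DataFrame."""
    import pandas as pd

    data = {}
    for label, seq in elements.items():
        data[label] = {g.id: count_element_copies(seq, g).count for g in genomes}
    return pd.DataFrame(data).T


def find_flanking_repeats(genome, interval: tuple[int, int], search_span: int = 5000,
                          min_len: int = 100, k: int = 16, min_id: float = 0.9) -> list[RepeatPair]:
    """Direct repeats with one copy just upstream and one just downstream of
    an interval (the cassette-flanking pattern of horizontally acquired
    operons)."""
    seq = genome.seq if isinstance(genome, GenomeRecord) else genome
    s, e = interval
    if not 0 <= s < e <= len(seq):
        raise ValueError("interval outside genome")
    ls = max(0, s - search_span)
    left = seq[ls:s]
    right = seq[e:min(len(seq), e + search_span)]
    if not left or not right:
        return []
    px, py = _seed_pairs(left, right, k=k, maxocc=200)
    out = []
    for x0, y0, ln in _merge_diag_seeds(px, py, k, merge_gap=2 * k):
        xs, ys, tot, mt = _xdrop_extend(left, right, x0, y0, ln)
        pid = mt / tot
        if tot >= min_len and pid >= min_id:
            out.append(RepeatPair((ls + xs, ls + xs + tot), (e + ys, e + ys + tot),
                                  "direct", tot, 100 * pid))
    merged = _merge_pairs_on_diag([(p.intervalA[0], p.intervalB[0], p.length,
                                    round(p.length * p.pct_id / 100)) for p in out])
    out = [RepeatPair((xs, xs + ln), (ys, ys + ln), "direct", ln, 100 * mt / ln)
           for xs, ys, ln, mt in merged]
    out.sort(key=lambda r: r.intervalA)
    return out


def group_element_families(seqs: dict, min_id: float = 0.9, min_cov: float = 0.9):
    """Cluster element sequences into families at >= min_id over >= min_cov
    of the shorter sequence (single-linkage). Returns {family_rep: [labels]}."""
    labels = sorted(seqs)
    parent = {l: l for l in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sa, sb = seqs[a], seqs[b]
            short, long_ = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
            best = None
            for cand in (short, revcomp(short)):
                res = edlib.align(cand, long_, mode="HW", task="path")
                if res["editDistance"] >= 0:
                    m, x, _i, _d = _cigar_stats(res["cigar"])
                    stats = (m / len(short), (m + x) / len(short))
                    if best is None or stats > best:
                        best = stats
            if best and best[0] >= min_id and best[1] >= min_cov:
                parent[find(a)] = find(b)

    fams: dict[str, list] = {}
    for l in labels:
        fams.setdefault(find(l), []).append(l)
    return fams


def write_repeats_bed(pairs: list[RepeatPair], path: str, chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            fh.write(f"{chrom}\t{p.intervalA[0]}\t{p.intervalA[1]}\trepeat{i}_{p.orientation}_a\n")
            fh.write(f"{chrom}\t{p.intervalB[0]}\t{p.intervalB[1]}\trepeat{i}_{p.orientation}_b\n")
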