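"""Anchor-based collinear pairwise whole-genome alignment and SNP extraction.

The aligner is built for sister genomes at >=99% core identity: maximal
exact matches seeded by k-mers unique in both genomes (MUM-like) are chained
per orientation by maximum-weight collinear chaining, and the short
inter-anchor gaps are closed by banded global alignment with unit scores
(match +1, mismatch -1, gap -2, linear). One-sided gaps larger than
``max_gap`` are reported as unaligned strain-specific insertions instead of
being forced into an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .genomeio import GenomeRecord, revcomp

NEG = np.int32(-(10 ** 9))

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A,C,G,T -> 0..3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class Anchor(NamedTuple):
    posA: int
    posB: int  # forward-strand start in B, also for reverse anchors
    length: int
    orientation: str  # 'forward' | 'reverse'


class Edit(NamedTuple):
    """One run of identical alignment columns.

    op is one of 'match', 'mismatch', 'insA' (bases only in A), 'insB'.
    Base strings are retained for mismatch runs only; lengths suffice for
    the rest and are recoverable from the genome sequences.
    """

    op: str
    length: int
    a: Optional[str] = None
    b: Optional[str] = None


@dataclass
class AlignmentBlock:
    """A collinear aligned segment pair with base-level edits.

    Edits run along genome A forward; for reverse-orientation blocks they
    run against the reverse complement of the B segment, whose forward-strand
    interval is stored in ``intervalB``.
    """

    intervalA: tuple[int, int]
    intervalB: tuple[int, int]
    orientation: str
    edits: list[Edit] = field(default_factory=list)

    def consumed(self) -> tuple[int, int]:
        ca = sum(e.length for e in self.edits if e.op != "insB")
        cb = sum(e.length for e in self.edits if e.op != "insA")
        return ca, cb

    def validate(self) -> None:
        ca, cb = self.consumed()
        if ca != self.intervalA[1] - self.intervalA[0]:
            raise ValueError("edit lengths do not cover intervalA")
        if cb != self.intervalB[1] - self.intervalB[0]:
            raise ValueError("edit lengths do not cover intervalB")
        for e1, e2 in zip(self.edits, self.edits[1:]):
            if e1.op == e2.op:
                raise ValueError("adjacent edits of the same type")

    def aligned_strings(self, seqA: str, seqB: str) -> tuple[str, str]:
        """Reconstruct the two aligned (gapped) strings of the block."""
        sA = seqA[self.intervalA[0]:self.intervalA[1]]
        sB = seqB[self.intervalB[0]:self.intervalB[1]]
        if self.orientation == "reverse":
            sB = revcomp(sB)
        outA, outB, ia, ib = [], [], 0, 0
        for e in self.edits:
            if e.op in ("match", "mismatch"):
                outA.append(sA[ia:ia + e.length]); ia += e.length
                outB.append(sB[ib:ib + e.length]); ib += e.length
            elif e.op == "insA":
                outA.append(sA[ia:ia + e.length]); ia += e.length
                outB.append("-" * e.length)
            else:
                outA.append("-" * e.length)
                outB.append(sB[ib:ib + e.length]); ib += e.length
        return "".join(outA), "".join(outB)


@dataclass
class UnalignedSegment:
    genome: str  # 'A' | 'B'
    start: int
    end: int
    reason: str  # 'strain_specific_insertion' | 'below_threshold'

    def __len__(self):
        return self.end - self.start


class IdentityReport(NamedTuple):
    aligned_len: int
    matches: int
    pct: float
    mode: str


def merge_edits(edits: list[Edit]) -> list[Edit]:
    """Coalesce adjacent edits of the same type."""
    out: list[Edit] = []
    for e in edits:
        if e.length == 0:
            continue
        if out and out[-1].op == e.op:
            prev = out[-1]
            out[-1] = Edit(
                e.op, prev.length + e.length,
                (prev.a or "") + (e.a or "") if e.op == "mismatch" else None,
                (prev.b or "") + (e.b or "") if e.op == "mismatch" else None,
            )
        else:
            out.append(e)
    return out


def edits_from_columns(alnA: str, alnB: str) -> list[Edit]:
    """Classify aligned-string columns into merged edit runs."""
    edits = []
    for ca, cb in zip(alnA, alnB):
        if ca == "-":
            edits.append(Edit("insB", 1))
        elif cb == "-":
            edits.append(Edit("insA", 1))
        elif ca == cb:
            edits.append(Edit("match", 1))
        else:
            edits.append(Edit("mismatch", 1, ca, cb))
    return merge_edits(edits)


def block_from_aligned(alnA: str, alnB: str, startA: int, startB: int,
                       orientation: str = "forward") -> AlignmentBlock:
    lenA = len(alnA) - alnA.count("-")
    lenB = len(alnB) - alnB.count("-")
    blk = AlignmentBlock(
        intervalA=(startA, startA + lenA),
        intervalB=(startB, startB + lenB),
        orientation=orientation,
        edits=edits_from_columns(alnA, alnB),
    )
    blk.validate()
    return blk


# ---------------------------------------------------------------------------
# banded global alignment with unit scores (match +1, mismatch -1, gap -2)
# ---------------------------------------------------------------------------

def banded_global(a: str, b: str, band: int = 200, free_ends: bool = False):
    """Global alignment of two strings with unit scores inside a band.

    The band covers diagonal offsets ``j - i`` in
    [min(0, len(b)-len(a)) - band, max(0, len(b)-len(a)) + band], so the main
    and shifted diagonals are always inside it. With ``band >= max(len(a),
    len(b))`` this is the full dynamic program. ``free_ends`` makes leading
    and trailing gaps free (end-free global mode, used for gene pairs).

    Returns ``(score, edits)`` where edits is a merged Edit list. Columns
    consumed by free end-gaps are reported as ordinary insA/insB edits but do
    not contribute to the score.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        edits = []
        if la:
            edits.append(Edit("insA", la))
        if lb:
            edits.append(Edit("insB", lb))
        return (0 if free_ends else -2 * (la + lb)), edits

    ca, cb = encode(a), encode(b)
    dlo = min(0, lb - la) - band
    dhi = max(0, lb - la) + band
    W = dhi - dlo + 1
    M = np.full((la + 1, W), NEG, dtype=np.int32)

    # row 0: j in [0, min(lb, dhi)]
    j0 = np.arange(0, min(lb, dhi) + 1)
    M[0, j0 - dlo] = 0 if free_ends else -2 * j0

    best_end = (-(10 ** 9), la, lb)  # (score, i, j) for free-end traceback
    for i in range(1, la + 1):
        jlo = max(0, i + dlo)
        jhi = min(lb, i + dhi)
        if jlo > jhi:
            continue
        cols = np.arange(jlo - i - dlo, jhi - i - dlo + 1)
        js = np.arange(jlo, jhi + 1)
        prev = M[i - 1]
        # diagonal: (i-1, j-1) is the same band column
        diag = np.full(cols.shape, NEG, dtype=np.int32)
        has_diag = js >= 1
        if has_diag.any():
            sub = np.where(
                (ca[i - 1] == cb[js[has_diag] - 1]) & (ca[i - 1] < 4) & (cb[js[has_diag] - 1] < 4),
                np.int32(1), np.int32(-1))
            diag[has_diag] = prev[cols[has_diag]] + sub
        # vertical: (i-1, j) is band column + 1
        up = np.full(cols.shape, NEG, dtype=np.int32)
        ok = cols + 1 < W
        up[ok] = prev[cols[ok] + 1] - 2
        cand = np.maximum(diag, up)
        if free_ends and js[0] == 0:
            cand[0] = max(cand[0], 0)
        # horizontal runs via running max of cand + 2*j (linear gap cost)
        t = np.maximum.accumulate(cand + 2 * js)
        row = np.maximum(cand, t - 2 * js)
        M[i, cols] = row
        if free_ends and js[-1] == lb:
            if row[-1] > best_end[0]:
                best_end = (int(row[-1]), i, lb)

    def cell(i, j):
        c = j - i - dlo
        if 0 <= c < W:
            return int(M[i, c])
        return int(NEG)

    if free_ends:
        # best over last row as well
        jlo = max(0, la + dlo)
        for j in range(jlo, min(lb, la + dhi) + 1):
            v = cell(la, j)
            if v > best_end[0] or (v == best_end[0] and (la, j) > best_end[1:]):
                best_end = (v, la, j)
        score, i, j = best_end
        tail: list[Edit] = []
        if i < la:
            tail.append(Edit("insA", la - i))
        if j < lb:
            tail.append(Edit("insB", lb - j))
    else:
        score, i, j = cell(la, lb), la, lb
        tail = []

    # traceback (prefer diagonal, then vertical, then horizontal)
    rev_edits: list[Edit] = []
    while i > 0 or j > 0:
        if free_ends and (i == 0 or j == 0):
            if i:
                rev_edits.append(Edit("insA", i))
            if j:
                rev_edits.append(Edit("insB", j))
            break
        here = cell(i, j)
        if i > 0 and j > 0:
            sub = 1 if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else -1
            if cell(i - 1, j - 1) + sub == here:
                op = "match" if sub == 1 else "mismatch"
                rev_edits.append(Edit(op, 1, a[i - 1] if sub == -1 else None,
                                      b[j - 1] if sub == -1 else None))
                i -= 1; j -= 1
                continue
        if i > 0 and cell(i - 1, j) - 2 == here:
            rev_edits.append(Edit("insA", 1, None, None))
            i -= 1
            continue
        if j > 0 and cell(i, j - 1) - 2 == here:
            rev_edits.append(Edit("insB", 1))
            j -= 1
            continue
        raise RuntimeError("traceback failed (band too narrow?)")

    edits = merge_edits(list(reversed(rev_edits)) + tail)
    return int(score), edits


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _kmer_hashes(code: np.ndarray, k: int):
    """Rolling 2-bit k-mer hashes; windows containing N flagged invalid."""
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = code[j:j + n]
        valid &= c < 4
        h = (h << np.uint64(2)) | c.astype(np.uint64)
    return h, valid


def _strand_aware_counts(code: np.ndarray, code_rc: np.ndarray, k: int):
    hf, vf = _kmer_hashes(code, k)
    hr, vr = _kmer_hashes(code_rc, k)
    pool = np.concatenate([hf[vf], hr[vr]])
    uniq, counts = np.unique(pool, return_counts=True)
    return hf, vf, uniq, counts


def _lookup_counts(values, uniq, counts):
    idx = np.searchsorted(uniq, values)
    idx = np.clip(idx, 0, len(uniq) - 1)
    found = uniq[idx] == values
    out = np.zeros(len(values), dtype=np.int64)
    out[found] = counts[idx[found]]
    return out


def _merge_diagonal_runs(pa: np.ndarray, pb: np.ndarray, k: int):
    """Merge k-mer matches lying consecutively on one diagonal into runs."""
    if len(pa) == 0:
        return []
    diag = pb.astype(np.int64) - pa.astype(np.int64)
    order = np.lexsort((pa, diag))
    pa, pb, diag = pa[order], pb[order], diag[order]
    breaks = np.flatnonzero((np.diff(diag) != 0) | (np.diff(pa) != 1))
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pa) - 1]])
    return [(int(pa[s]), int(pb[s]), int(pa[e] - pa[s]) + k) for s, e in zip(starts, ends)]


def _extend_maximal(runs, sa: str, sb: str):
    out = []
    for pa, pb, ln in runs:
        while pa > 0 and pb > 0 and sa[pa - 1] == sb[pb - 1] and sa[pa - 1] in "ACGT":
            pa -= 1; pb -= 1; ln += 1
        ea, eb = pa + ln, pb + ln
        la, lb = len(sa), len(sb)
        while ea < la and eb < lb and sa[ea] == sb[eb] and sa[ea] in "ACGT":
            ea += 1; eb += 1; ln += 1
        out.append((pa, pb, ln))
    return out


def find_anchors(seqA: str, seqB: str, k: int = 20) -> list[Anchor]:
    """Maximal exact matches seeded by k-mers unique in both genomes.

    Uniqueness is strand-aware (a k-mer and its reverse complement are
    counted together within each genome), so anchors never fall inside
    multi-copy repeats such as IS elements. Both orientations are returned.
    """
    if k < 12:
        raise ValueError("k must be >= 12")
    if not seqA or not seqB:
        raise ValueError("sequences must be non-empty")
    cA, cB = encode(seqA), encode(seqB)
    rcA, rcB = revcomp(seqA), revcomp(seqB)
    cAr, cBr = encode(rcA), encode(rcB)

    hA, vA, uniqA, cntA = _strand_aware_counts(cA, cAr, k)
    hB, vB, uniqB, cntB = _strand_aware_counts(cB, cBr, k)
    hBr, vBr = _kmer_hashes(cBr, k)

    selA = vA.copy()
    selA[vA] &= _lookup_counts(hA[vA], uniqA, cntA) == 1
    selA[vA] &= _lookup_counts(hA[vA], uniqB, cntB) == 1
    posA = np.flatnonzero(selA)
    valsA = hA[posA]
    orderA = np.argsort(valsA, kind="stable")
    valsA_sorted, posA_sorted = valsA[orderA], posA[orderA]

    def _match_positions(hX, vX):
        posX = np.flatnonzero(vX)
        valsX = hX[posX]
        idx = np.searchsorted(valsA_sorted, valsX)
        idx = np.clip(idx, 0, len(valsA_sorted) - 1)
        hitmask = (len(valsA_sorted) > 0) & (valsA_sorted[idx] == valsX) if len(valsA_sorted) else \
            np.zeros(len(valsX), dtype=bool)
        return posA_sorted[idx[hitmask]], posX[hitmask]

    anchors: list[Anchor] = []
    # forward: A vs B
    fa, fb = _match_positions(hB, vB)
    for pa, pb, ln in _extend_maximal(_merge_diagonal_runs(fa, fb, k), seqA, seqB):
        anchors.append(Anchor(pa, pb, ln, "forward"))
    # reverse: A vs rc(B); map back to forward coordinates of B
    ra, rb = _match_positions(hBr, vBr)
    LB = len(seqB)
    for pa, pbr, ln in _extend_maximal(_merge_diagonal_runs(ra, rb, k), seqA, rcB):
        anchors.append(Anchor(pa, LB - (pbr + ln), ln, "reverse"))
    anchors = sorted(set(anchors), key=lambda x: (x.posA, x.posB))
    return anchors


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

class _FenwickMax:
    """Prefix-max Fenwick tree carrying an argmax payload."""

    def __init__(self, n: int):
        self.val = [float("-inf")] * (n + 1)
        self.arg = [-1] * (n + 1)

    def update(self, i: int, v: float, a: int):
        i += 1
        while i < len(self.val):
            if v > self.val[i]:
                self.val[i] = v
                self.arg[i] = a
            i += i & (-i)

    def query(self, i: int):
        """Max over indices [0, i]."""
        i += 1
        best, arg = float("-inf"), -1
        while i > 0:
            if self.val[i] > best:
                best, arg = self.val[i], self.arg[i]
            i -= i & (-i)
        return best, arg


def _chain_lis(anchors: list[Anchor], max_overlap: int = 100) -> tuple[list[Anchor], int]:
    """Maximum-weight collinear chain (both coordinates increasing).

    Weight is anchor length; ties broken toward smaller posA by processing
    order. Successive anchors may overlap by up to ``max_overlap`` bp (exact
    matches can extend a few bases past a true breakpoint by chance); the
    consumer trims such overlaps. O(n log n) via a Fenwick tree over B end
    positions.
    """
    import heapq
    from bisect import bisect_right

    if not anchors:
        return [], 0
    anchors = sorted(anchors, key=lambda x: (x.posA, x.posB))
    endsB = sorted({a.posB + a.length for a in anchors})
    fen = _FenwickMax(len(endsB))
    n = len(anchors)
    best = [0] * n
    parent = [-1] * n
    # sweep by posA; a processed anchor becomes a usable predecessor once its
    # A interval is closed (within the overlap tolerance)
    pending: list[tuple[int, int]] = []  # (endA, index), processed anchors only
    for i in range(n):
        a = anchors[i]
        while pending and pending[0][0] <= a.posA + max_overlap:
            _, j = heapq.heappop(pending)
            fen.update(bisect_right(endsB, anchors[j].posB + anchors[j].length) - 1, best[j], j)
        # predecessors must end at or before our posB (within the tolerance)
        r = bisect_right(endsB, a.posB + max_overlap) - 1
        q, arg = fen.query(r) if r >= 0 else (float("-inf"), -1)
        if arg >= 0 and q > 0:
            best[i] = q + a.length
            parent[i] = arg
        else:
            best[i] = a.length
        heapq.heappush(pending, (a.posA + a.length, i))
    top = max(range(n), key=lambda i: (best[i], -anchors[i].posA))
    chain = []
    i = top
    while i >= 0:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return chain, best[top]


def _to_rc_space(a: Anchor, LB: int) -> Anchor:
    return Anchor(a.posA, LB - (a.posB + a.length), a.length, a.orientation)


def chain_anchors(anchors: list[Anchor], genome_b_length: Optional[int] = None) -> list[dict]:
    """Select maximum-weight collinear chains, one list of anchors per chain.

    Forward anchors are chained in (posA, posB); reverse anchors are chained
    in reverse-complement B space (where an inversion is collinear). Reverse
    anchors conflicting with the forward chain are discarded, and the kept
    anchors are split into maximal collinear runs of constant orientation.
    Returns a list of ``{"orientation": ..., "anchors": [...]}`` chains
    ordered by posA.
    """
    fwd = [a for a in anchors if a.orientation == "forward"]
    rev = [a for a in anchors if a.orientation == "reverse"]
    chainF, _ = _chain_lis(fwd)
    if rev:
        LB = genome_b_length
        if LB is None:
            LB = max(a.posB + a.length for a in rev)
        rc = [_to_rc_space(a, LB) for a in rev]
        chainR_rc, _ = _chain_lis(rc)
        chainR = [_to_rc_space(a, LB) for a in chainR_rc]  # involution back
    else:
        chainR = []

    # Forward anchors extend through the mediating repeat copy into an
    # inverted segment (the seam of a repeat-mediated inversion is seamless
    # inside the repeat), so reverse anchors are trimmed where the forward
    # chain already covers them rather than dropped. For a reverse anchor an
    # A-front trim consumes the B interval's end and vice versa.
    def _trim_reverse(r: Anchor) -> Optional[Anchor]:
        front = back = 0
        for f in chainF:
            fendA, fendB = f.posA + f.length, f.posB + f.length
            rendA, rendB = r.posA + r.length, r.posB + r.length
            if f.posA <= r.posA < fendA:
                front = max(front, fendA - r.posA)
            if r.posA < f.posA < rendA:
                back = max(back, rendA - f.posA)
            if f.posB <= r.posB < fendB:
                back = max(back, fendB - r.posB)
            if r.posB < f.posB < rendB:
                front = max(front, rendB - f.posB)
        if front + back >= r.length:
            return None
        return Anchor(r.posA + front, r.posB + back, r.length - front - back, r.orientation)

    chainR = [t for r in chainR if (t := _trim_reverse(r)) is not None]

    kept = sorted(chainF + chainR, key=lambda x: x.posA)
    chains: list[dict] = []
    for a in kept:
        if chains and chains[-1]["orientation"] == a.orientation:
            prev = chains[-1]["anchors"][-1]
            if a.orientation == "forward":
                collinear = a.posB >= prev.posB + prev.length - 100
            else:
                collinear = a.posB + a.length <= prev.posB + 100
            if collinear:
                chains[-1]["anchors"].append(a)
                continue
        chains.append({"orientation": a.orientation, "anchors": [a]})
    return chains


# ---------------------------------------------------------------------------
# gap closing
# ---------------------------------------------------------------------------

def close_gaps(chains: list[dict], seqA: str, seqB: str,
               max_gap: int = 5000, band: int = 200,
               gap_min_identity: float = 0.75, gap_check_min_len: int = 30):
    """Close inter-anchor gaps into AlignmentBlocks; large one-sided gaps
    become UnalignedSegments.

    A gap is aligned when both sides are <= max_gap; otherwise the block is
    split there and each non-empty side is reported unaligned (reason
    strain_specific_insertion when its length exceeds max_gap, else
    below_threshold). An aligned gap with both sides >= ``gap_check_min_len``
    whose identity falls below ``gap_min_identity`` is non-orthologous
    sequence (e.g. different elements inserted near the same spot in the two
    strains); it is demoted to below_threshold unaligned segments rather
    than reported as a wall of spurious mismatches. Genome spans outside
    every block are reported the same way afterwards.
    """
    if max_gap < band or band < 1:
        raise ValueError("require max_gap >= band >= 1")
    blocks: list[AlignmentBlock] = []
    unaligned: list[UnalignedSegment] = []
    LB = len(seqB)

    for chain in chains:
        orientation = chain["orientation"]
        if orientation == "forward":
            sB = seqB
            anchors = chain["anchors"]
        else:
            sB = revcomp(seqB)
            anchors = [_to_rc_space(a, LB) for a in chain["anchors"]]
            anchors.sort(key=lambda x: x.posA)

        def _flush(startA, startB, edits):
            if not edits:
                return
            edits = merge_edits(edits)
            ca = sum(e.length for e in edits if e.op != "insB")
            cb = sum(e.length for e in edits if e.op != "insA")
            if orientation == "forward":
                ib = (startB, startB + cb)
            else:
                ib = (LB - (startB + cb), LB - startB)
            blk = AlignmentBlock((startA, startA + ca), ib, orientation, edits)
            blk.validate()
            blocks.append(blk)

        def _unal(genome, s, e):
            if e > s:
                reason = ("strain_specific_insertion" if e - s > max_gap
                          else "below_threshold")
                if genome == "B" and orientation == "reverse":
                    s, e = LB - e, LB - s
                unaligned.append(UnalignedSegment(genome, s, e, reason))

        cur_edits: list[Edit] = []
        cur_startA = cur_startB = None
        prev = None
        for a in anchors:
            if prev is not None:
                # trim chance overlap with the previous anchor (both are
                # exact matches, so trimming the front keeps the invariant)
                d = max(prev.posA + prev.length - a.posA,
                        prev.posB + prev.length - a.posB, 0)
                if d >= a.length:
                    continue
                if d:
                    a = Anchor(a.posA + d, a.posB + d, a.length - d, a.orientation)
            if prev is None:
                cur_startA, cur_startB = a.posA, a.posB
            else:
                gA0, gA1 = prev.posA + prev.length, a.posA
                gB0, gB1 = prev.posB + prev.length, a.posB
                la, lb = gA1 - gA0, gB1 - gB0
                aligned_ok = False
                if la <= max_gap and lb <= max_gap:
                    gap_edits = []
                    if la or lb:
                        _, gap_edits = banded_global(seqA[gA0:gA1], sB[gB0:gB1], band=band)
                    aligned_ok = True
                    if min(la, lb) >= gap_check_min_len:
                        gmatch = sum(e.length for e in gap_edits if e.op == "match")
                        if gmatch < gap_min_identity * max(la, lb):
                            aligned_ok = False
                    if aligned_ok:
                        cur_edits.extend(gap_edits)
                if not aligned_ok:
                    _flush(cur_startA, cur_startB, cur_edits)
                    _unal("A", gA0, gA1)
                    _unal("B", gB0, gB1)
                    cur_edits = []
                    cur_startA, cur_startB = a.posA, a.posB
            cur_edits.append(Edit("match", a.length))
            prev = a
        _flush(cur_startA, cur_startB, cur_edits)

    # residual uncovered spans in each genome
    for name, L in (("A", len(seqA)), ("B", LB)):
        covered = sorted(
            [(blk.intervalA if name == "A" else blk.intervalB) for blk in blocks]
            + [(u.start, u.end) for u in unaligned if u.genome == name]
        )
        pos = 0
        gaps = []
        for s, e in covered:
            if s > pos:
                gaps.append((pos, s))
            pos = max(pos, e)
        if pos < L:
            gaps.append((pos, L))
        for s, e in gaps:
            reason = "strain_specific_insertion" if e - s > max_gap else "below_threshold"
            unaligned.append(UnalignedSegment(name, s, e, reason))

    unaligned.sort(key=lambda u: (u.genome, u.start))
    blocks.sort(key=lambda b: b.intervalA)
    return blocks, unaligned


def align_genomes(genomeA: GenomeRecord, genomeB: GenomeRecord,
                  k: int = 20, max_gap: int = 5000, band: int = 200):
    """Anchor, chain, and gap-close two genomes; returns (blocks, unaligned).

    Circular genomes are aligned on their linearized sequence with the
    origin as the cut point; sister genomes derived from one ancestor share
    that cut, so no junction-spanning block is attempted.
    """
    anchors = find_anchors(genomeA.seq, genomeB.seq, k=k)
    chains = chain_anchors(anchors, genome_b_length=len(genomeB.seq))
    return close_gaps(chains, genomeA.seq, genomeB.seq, max_gap=max_gap, band=band)


# ---------------------------------------------------------------------------
# SNP extraction and identity
# ---------------------------------------------------------------------------

def call_snps(blocks: list[AlignmentBlock], genomeA=None, genomeB=None):
    """One SNPRecord per mismatch column, positions in both genomes.

    Mismatch columns involving N are excluded and counted separately.
    For reverse-orientation blocks ``baseB`` is the aligned (reverse-strand)
    base while ``posB`` is the forward-strand coordinate in genome B.
    Returns (records, n_excluded).
    """
    from .variants import SNPRecord

    records = []
    n_excluded = 0
    for blk in blocks:
        ia = blk.intervalA[0]
        ib = 0  # consumed B, in alignment orientation
        for e in blk.edits:
            if e.op == "mismatch":
                for t in range(e.length):
                    ba, bb = e.a[t], e.b[t]
                    if ba == "N" or bb == "N":
                        n_excluded += 1
                        continue
                    if blk.orientation == "forward":
                        pb = blk.intervalB[0] + ib + t
                    else:
                        pb = blk.intervalB[1] - 1 - (ib + t)
                    records.append(SNPRecord(posA=ia + t, posB=pb, baseA=ba, baseB=bb))
            if e.op != "insB":
                ia += e.length
            if e.op != "insA":
                ib += e.length
    records.sort(key=lambda r: r.posA)
    return records, n_excluded


def identity(blocks: list[AlignmentBlock], unaligned: list[UnalignedSegment],
             mode: str = "core") -> IdentityReport:
    """Percent identity of a pairwise alignment.

    mode='core': matches over match+mismatch columns only (indel columns and
    unaligned segments excluded) — the identity of the collinear core.
    mode='whole': matches over all alignment columns plus the lengths of
    unaligned segments of both genomes — a whole-genome average nucleotide
    identity that large strain-specific insertions drag down.
    """
    if mode not in ("core", "whole"):
        raise ValueError(f"unknown mode {mode!r}")
    if not blocks:
        raise ValueError("empty alignment")
    matches = sum(e.length for b in blocks for e in b.edits if e.op == "match")
    mism = sum(e.length for b in blocks for e in b.edits if e.op == "mismatch")
    gapcols = sum(e.length for b in blocks for e in b.edits if e.op in ("insA", "insB"))
    if mode == "core":
        denom = matches + mism
        aligned_len = denom
    else:
        denom = matches + mism + gapcols + sum(len(u) for u in unaligned)
        aligned_len = matches + mism + gapcols
    if denom == 0:
        raise ValueError("empty alignment")
    return IdentityReport(aligned_len, matches, 100.0 * matches / denom, mode)


def write_unaligned_bed(unaligned, path: str, nameA: str = "A", nameB: str = "B") -> None:
    with open(path, "w") as fh:
        for u in unaligned:
            chrom = nameA if u.genome == "A" else nameB
            fh.write(f"{chrom}\t{u.start}\t{u.end}\t{u.reason}\n")
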