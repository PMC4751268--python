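"""Reciprocal-best-hit ortholog calling with a built-in protein search.

The built-in search is a word-seeded, banded Smith-Waterman under BLOSUM62
with affine gaps (open 11, extend 1). Raw scores S are converted to bit
scores S' = (lambda*S - ln K)/ln 2 with the classical ungapped-regime
constants lambda = 0.267, K = 0.041 held fixed (recorded in output headers:
e-values are comparator-sensitive), and E = m*n*2^(-S') with m the query
length and n the total residue count of the target set. External 12-column
tabular hits can be supplied instead and are then authoritative.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional

import numpy as np
from Bio.Align import substitution_matrices

from .genomeio import Hit

LAMBDA = 0.267
K_PARAM = 0.041
NEG = np.int32(-(10 ** 9))

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = "".join(_B62.alphabet)
_AA_CODE = np.full(256, _ALPHA.index("X"), dtype=np.uint8)
for _i, _c in enumerate(_ALPHA):
    _AA_CODE[ord(_c)] = _i
_SUB = np.array(_B62, dtype=np.int32)

GAP_OPEN = 11
GAP_EXTEND = 1
SEED_K = 5


class OrthologPair(NamedTuple):
    locusA: str
    locusB: str
    evalueAB: float
    evalueBA: float
    bitscoreAB: float
    bitscoreBA: float


def encode_protein(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def bitscore(raw: float) -> float:
    return (LAMBDA * raw - math.log(K_PARAM)) / math.log(2.0)


def evalue(raw: float, m: int, n: int) -> float:
    return m * n * math.pow(2.0, -bitscore(raw))


def local_affine(a: str, b: str, band: Optional[tuple[int, int]] = None):
    """Banded Smith-Waterman, BLOSUM62, affine gaps (open 11, extend 1).

    ``band`` restricts diagonal offsets j - i to [dlo, dhi]; None means the
    full matrix. Returns (score, n_matches, aligned_cols, (ai, aj, bi, bj))
    — the raw score, identities and column count of the best local
    alignment, and its half-open query/target spans.
    """
    la, lb = len(a), len(b)
    ca, cb = encode_protein(a), encode_protein(b)
    if band is None:
        dlo, dhi = -la, lb
    else:
        dlo, dhi = band
        dlo = max(dlo, -la)
        dhi = min(dhi, lb)
    W = dhi - dlo + 1
    H = np.zeros((la + 1, W), dtype=np.int32)
    F = np.full((la + 1, W), NEG, dtype=np.int32)
    valid = np.zeros((la + 1, W), dtype=bool)
    j0 = np.arange(max(0, dlo), min(lb, dhi) + 1)
    valid[0, j0 - dlo] = True
    best = (0, 0, 0)
    for i in range(1, la + 1):
        jlo = max(0, i + dlo)
        jhi = min(lb, i + dhi)
        if jlo > jhi:
            continue
        js = np.arange(jlo, jhi + 1)
        cols = js - i - dlo
        prevH, prevF = H[i - 1], F[i - 1]
        # diagonal (same band column), invalid outside previous row's range
        diag = np.full(len(js), NEG, dtype=np.int32)
        hd = js >= 1
        if hd.any():
            pj = js[hd] - 1
            in_prev = (pj >= max(0, i - 1 + dlo)) & (pj <= min(lb, i - 1 + dhi))
            sub = _SUB[ca[i - 1], cb[pj[in_prev]]]
            tmp = np.full(int(hd.sum()), NEG, dtype=np.int32)
            tmp[in_prev] = prevH[cols[hd][in_prev]] + sub
            diag[hd] = tmp
        # vertical: (i-1, j) -> band column + 1
        up_ok = cols + 1 < W
        Fi = np.full(len(js), NEG, dtype=np.int32)
        Fi[up_ok] = np.maximum(prevH[cols[up_ok] + 1] - GAP_OPEN,
                               prevF[cols[up_ok] + 1] - GAP_EXTEND)
        H0 = np.maximum(0, np.maximum(diag, Fi))
        # horizontal gap of length g >= 1 costs open + (g-1)*extend; with
        # extend = 1 this is a running max of H0[j'] + j' shifted by -open-(j-1)
        t = np.maximum.accumulate(H0 + js)
        Ei = np.concatenate(([NEG], t[:-1])) - GAP_OPEN - (js - 1)
        Hrow = np.maximum(H0, Ei).astype(np.int32)
        H[i, cols] = Hrow
        F[i, cols] = Fi
        valid[i, cols] = True
        mx = int(Hrow.max(initial=0))
        if mx > best[0]:
            jbest = int(js[int(np.argmax(Hrow))])
            best = (mx, i, jbest)

    score, bi, bj = best
    if score <= 0:
        return 0, 0, 0, (0, 0, 0, 0)

    def cell(mat, i, j):
        c = j - i - dlo
        if 0 <= c < W and valid[i, c]:
            return int(mat[i, c])
        return int(NEG)

    # traceback from the best cell through H/F and the implicit E state
    i, j = bi, bj
    n_match = cols_count = 0
    state = "H"
    ei, ej = bi, bj
    while i > 0 and j > 0:
        h = cell(H, i, j)
        if state == "H":
            if h == 0:
                break
            sub = int(_SUB[ca[i - 1], cb[j - 1]])
            if cell(H, i - 1, j - 1) + sub == h:
                cols_count += 1
                if ca[i - 1] == cb[j - 1]:
                    n_match += 1
                i -= 1; j -= 1
                continue
            if cell(F, i, j) == h:
                state = "F"
                continue
            # horizontal gap: walk left until an opening cell matches
            g = 1
            while j - g > 0:
                if cell(H, i, j - g) - GAP_OPEN - (g - 1) * GAP_EXTEND == h:
                    break
                g += 1
            cols_count += g
            j -= g
            continue
        else:  # F state: vertical gap
            f = cell(F, i, j)
            cols_count += 1
            if cell(H, i - 1, j) - GAP_OPEN == f:
                state = "H"
            i -= 1
            continue
    return score, n_match, cols_count, (i, bi, j, bj)


def _seed_index(proteins: dict, k: int = SEED_K):
    index: dict[int, list] = {}
    for name, seq in proteins.items():
        c = encode_protein(seq)
        if len(c) < k:
            continue
        h = np.zeros(len(c) - k + 1, dtype=np.int64)
        for j in range(k):
            h = h * 32 + c[j:j + len(c) - k + 1]
        for pos, val in enumerate(h.tolist()):
            index.setdefault(val, []).append((name, pos))
    return index


def protein_search(queries: dict, targets: dict, max_evalue: float = 10.0,
                   band_pad: int = 32, k: int = SEED_K) -> list[Hit]:
    """Word-seeded banded local search of every query against the targets.

    Candidate (query, target) pairs share at least one exact k-mer (k=5);
    each is scored by banded affine local alignment with the band spanning
    all shared-seed diagonals plus ``band_pad``. Hits are returned sorted by
    query, then e-value, ties by subject id.
    """
    if not queries or not targets:
        raise ValueError("empty proteome")
    tindex = _seed_index(targets, k)
    n_db = sum(len(s) for s in targets.values())
    hits: list[Hit] = []
    for qname in sorted(queries):
        qseq = queries[qname]
        c = encode_protein(qseq)
        if len(c) < k:
            continue
        h = np.zeros(len(c) - k + 1, dtype=np.int64)
        for j in range(k):
            h = h * 32 + c[j:j + len(c) - k + 1]
        diags: dict[str, list[int]] = {}
        for qpos, val in enumerate(h.tolist()):
            for tname, tpos in tindex.get(val, ()):
                diags.setdefault(tname, []).append(tpos - qpos)
        qhits = []
        for tname, ds in diags.items():
            band = (min(ds) - band_pad, max(ds) + band_pad)
            score, n_match, cols, _spans = local_affine(qseq, targets[tname], band)
            if score <= 0:
                continue
            e = evalue(score, len(qseq), n_db)
            if e <= max_evalue:
                pct = 100.0 * n_match / cols if cols else 0.0
                qhits.append(Hit(qname, tname, pct, cols, e, bitscore(score)))
        qhits.sort(key=lambda x: (x.evalue, -x.bitscore, x.subject))
        hits.extend(qhits)
    return hits


def best_hits(hits: list[Hit], evalue_cutoff: float) -> dict:
    """Best subject per query after the e-value filter (filter-then-best).

    Best = lowest e-value, tie highest bitscore, tie lexicographically
    smallest subject id.
    """
    best: dict[str, Hit] = {}
    for h in hits:
        if h.evalue > evalue_cutoff:
            continue
        cur = best.get(h.query)
        if cur is None or (h.evalue, -h.bitscore, h.subject) < (cur.evalue, -cur.bitscore, cur.subject):
            best[h.query] = h
    return best


def reciprocal_best_hits(hitsAB: list[Hit], hitsBA: list[Hit],
                         evalue_cutoff: float = 1e-10) -> list[OrthologPair]:
    """Pairs (a, b) where b is a's best hit, a is b's best hit, and both
    e-values pass the cutoff. The within-genus cutoff used for these genomes
    is 1e-10; cross-genus comparisons use 1e-5."""
    bestAB = best_hits(hitsAB, evalue_cutoff)
    bestBA = best_hits(hitsBA, evalue_cutoff)
    pairs = []
    for a, hab in sorted(bestAB.items()):
        b = hab.subject
        hba = bestBA.get(b)
        if hba is not None and hba.subject == a:
            pairs.append(OrthologPair(a, b, hab.evalue, hba.evalue,
                                      hab.bitscore, hba.bitscore))
    return pairs


def proteome_of(genome) -> dict:
    """locus_tag -> translated protein for codon-clean CDS features."""
    from .genomeio import translate_cds

    out = {}
    for f in genome.cds(include_excluded=False):
        if f.translation:
            out[f.locus_tag] = f.translation
        elif len(f) % 3 == 0:
            out[f.locus_tag] = translate_cds(genome.feature_seq(f))
    return out


def write_ortholog_pairs(pairs: list[OrthologPair], path: str,
                         evalue_cutoff: float = 1e-10) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reciprocal best hits; evalue_cutoff={evalue_cutoff:g}; "
                 f"karlin-altschul lambda={LAMBDA} K={K_PARAM}\n")
        fh.write("locusA\tlocusB\tevalueAB\tevalueBA\tbitscoreAB\tbitscoreBA\n")
        for p in pairs:
            fh.write(f"{p.locusA}\t{p.locusB}\t{p.evalueAB:.3e}\t{p.evalueBA:.3e}\t"
                     f"{p.bitscoreAB:.1f}\t{p.bitscoreBA:.1f}\n")
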