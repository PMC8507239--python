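"""Seed-chain-extend local alignment producing identity-scored blocks.

This is the single alignment substrate behind ANI, marker detection,
chimera cleaning, guided binning, guided merging and coverage. The pipeline
operates in a near-identity regime (>=90% identity between sequences of the
same strain group), so the aligner trades homology-search sensitivity for
speed: exact k-mer seeds, single-diagonal-band chaining, gap-free X-drop end
extension, and a final edit-distance pass (edlib) that recomputes identity
from the actual alignment rather than estimating it from seeds.

Identity convention: matches / aligned columns, gaps included in the
denominator (the blastn/ANI convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .seqio import Contig, GenomeAssembly, ReadRecord, revcomp

# diagonal band width for chaining; seeds chain when their diagonals agree
# within this drift and their query gap is at most _CHAIN_GAP
_BAND = 50
_CHAIN_GAP = 500
_XDROP = 20
_MATCH, _MISMATCH = 1, -2

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and integer codes of all k-mers without N."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win >= 0).all(axis=1)
    pos = np.flatnonzero(valid)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    codes = win[pos].astype(np.uint64) @ powers
    return pos.astype(np.int64), codes


@dataclass
class AlignmentBlock:
    """One local alignment between a query and a target interval."""

    query_id: str
    q_start: int
    q_end: int
    target_id: str
    t_start: int
    t_end: int
    strand: str
    identity: float
    aln_len: int

    @property
    def matches(self) -> int:
        return round(self.identity * self.aln_len)


class SeedIndex:
    """Exact-match k-mer index over the forward strand of a target assembly.

    Reverse-complement hits are found by looking up the reverse-complemented
    query, so the index itself stays single-stranded. Contigs are concatenated
    with k N separators; k-mers containing N are never indexed, hence no seed
    spans a contig boundary.
    """

    def __init__(self, targets: GenomeAssembly, k: int = 15):
        if not 11 <= k <= 21:
            raise ValueError(f"k={k} outside [11, 21]")
        if not targets.contigs:
            raise ValueError("cannot index an empty assembly")
        self.k = k
        self.contig_ids = [c.id for c in targets.contigs]
        sep = "N" * k
        parts, starts, off = [], [], 0
        for c in targets.contigs:
            starts.append(off)
            parts.append(c.seq)
            off += len(c.seq) + k
            parts.append(sep)
        self.seq = "".join(parts)
        self.arr = _encode(self.seq)
        self.starts = np.array(starts, dtype=np.int64)
        self.lengths = np.array([len(c.seq) for c in targets.contigs], dtype=np.int64)
        pos, codes = _kmer_codes(self.arr, k)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query k-mer index, target position) hit pairs, vectorized."""
        lo = np.searchsorted(self.codes, codes, "left")
        hi = np.searchsorted(self.codes, codes, "right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qidx = np.repeat(np.arange(codes.size), counts)
        ramp = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        tpos = self.pos[np.repeat(lo, counts) + ramp]
        return qidx, tpos

    def contig_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.starts, gpos, "right") - 1)

    def bounds(self, ci: int) -> tuple[int, int]:
        s = int(self.starts[ci])
        return s, s + int(self.lengths[ci])


def _xdrop_extend(qarr: np.ndarray, tarr: np.ndarray, qe: int, te: int,
                  q_hi: int, t_hi: int, step: int) -> int:
    """Gap-free X-drop extension; returns the best-scoring extension length.

    With ``step=+1`` extends right from (qe, te) up to (q_hi, t_hi) exclusive;
    with ``step=-1`` extends left from (qe, te) down to the (q_hi, t_hi)
    inclusive bounds. Stopping at the best-scoring point trims trailing
    mismatch runs, which keeps breakpoints (e.g. chimera junctions) tight.
    """
    score = best = 0
    best_i = 0
    i = 0
    if step > 0:
        limit = min(q_hi - qe, t_hi - te)
    else:
        limit = min(qe - q_hi, te - t_hi)
    while i < limit:
        q = qarr[qe + step * i] if step > 0 else qarr[qe - 1 - i]
        t = tarr[te + step * i] if step > 0 else tarr[te - 1 - i]
        score += _MATCH if (q == t and q >= 0) else _MISMATCH
        i += 1
        if score > best:
            best, best_i = score, i
        elif score < best - _XDROP:
            break
    return best_i


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, aligned columns) from an edlib extended CIGAR."""
    matches = columns = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            columns += num
            if ch == "=":
                matches += num
            num = 0
    return matches, columns


def _chains_for_strand(qarr: np.ndarray, index: SeedIndex) -> list[tuple[int, int, int, int]]:
    """Chained seed cores as (q_lo, q_hi, t_lo, t_hi) concat-coordinate spans."""
    k = index.k
    pos, codes = _kmer_codes(qarr, k)
    if pos.size == 0:
        return []
    qidx, tpos = index.lookup(codes)
    if qidx.size == 0:
        return []
    qp = pos[qidx]
    diag = tpos - qp
    band = diag // _BAND
    ci = np.searchsorted(index.starts, tpos, side="right") - 1
    order = np.lexsort((qp, band, ci))
    qp, tpos, band, ci = qp[order], tpos[order], band[order], ci[order]
    brk = np.flatnonzero((np.diff(ci) != 0) | (np.diff(band) != 0)
                         | (np.diff(qp) > _CHAIN_GAP)) + 1
    chains = []
    for s, e in zip(np.r_[0, brk], np.r_[brk, qp.size]):
        cq, ct = qp[s:e], tpos[s:e]
        q_lo, q_hi = int(cq.min()), int(cq.max()) + k
        t_lo, t_hi = int(ct.min()), int(ct.max()) + k
        chains.append((q_lo, q_hi, t_lo, t_hi))
    return chains


def _blocks_for_strand(query_id: str, qarr: np.ndarray, qseq: str, qlen: int,
                       index: SeedIndex, strand: str,
                       min_identity: float, min_len: int) -> list[AlignmentBlock]:
    blocks = []
    for q_lo, q_hi, t_lo, t_hi in _chains_for_strand(qarr, index):
        ci = index.contig_of(t_lo)
        c_lo, c_hi = index.bounds(ci)
        t_hi = min(t_hi, c_hi)  # guard: clip to the seed's contig
        ext_r = _xdrop_extend(qarr, index.arr, q_hi, t_hi, qlen, c_hi, +1)
        ext_l = _xdrop_extend(qarr, index.arr, q_lo, t_lo, 0, c_lo, -1)
        qs, qe = q_lo - ext_l, q_hi + ext_r
        ts, te = t_lo - ext_l, t_hi + ext_r
        res = edlib.align(qseq[qs:qe], index.seq[ts:te], task="path")
        matches, columns = _cigar_stats(res["cigar"])
        if columns == 0:
            continue
        identity = matches / columns
        if identity < min_identity or columns < min_len:
            continue
        t0 = ts - c_lo
        if strand == "+":
            b = AlignmentBlock(query_id, qs, qe, index.contig_ids[ci],
                               t0, t0 + (te - ts), "+", identity, columns)
        else:
            b = AlignmentBlock(query_id, qlen - qe, qlen - qs, index.contig_ids[ci],
                               t0, t0 + (te - ts), "-", identity, columns)
        blocks.append(b)
    return blocks


def _prune(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Keep one evidence unit per target locus.

    Blocks overlapping >50% (of the shorter) on the same target contig are
    pruned, keeping the highest identity x length. Distinct target loci hit by
    the same query region survive, so duplicated loci remain countable.
    """
    blocks = sorted(blocks, key=lambda b: (-b.identity * b.aln_len, b.target_id,
                                           b.t_start, b.q_start, b.strand))
    kept: list[AlignmentBlock] = []
    for b in blocks:
        redundant = False
        for o in kept:
            if o.target_id != b.target_id:
                continue
            ov = min(b.t_end, o.t_end) - max(b.t_start, o.t_start)
            if ov > 0.5 * min(b.t_end - b.t_start, o.t_end - o.t_start):
                redundant = True
                break
        if not redundant:
            kept.append(b)
    return kept


def align(query: Contig | ReadRecord, index: SeedIndex,
          min_identity: float = 0.9, min_len: int = 100) -> list[AlignmentBlock]:
    """Local alignment blocks of ``query`` against the indexed targets.

    Blocks are found by k-mer seeding, diagonal chaining and banded end
    extension; identity is recomputed from the final edit path. Returns only
    blocks with ``identity >= min_identity`` and ``aln_len >= min_len``,
    pruned to one block per target locus. An empty list is a valid result.
    """
    qseq = query.seq
    qlen = len(qseq)
    if qlen < min_len:
        return []
    fwd = _encode(qseq)
    rseq = revcomp(qseq)
    rev = _encode(rseq)
    blocks = _blocks_for_strand(query.id, fwd, qseq, qlen, index, "+", min_identity, min_len)
    blocks += _blocks_for_strand(query.id, rev, rseq, qlen, index, "-", min_identity, min_len)
    return _prune(blocks)


def map_read(read: ReadRecord, index: SeedIndex, min_frag: int = 30,
             min_identity: float = 0.9) -> list[AlignmentBlock]:
    """Short-query mapping (smaller default k belongs to the index; see
    :func:`read_index`). Blocks sorted by query start."""
    blocks = align(read, index, min_identity=min_identity, min_len=min_frag)
    return sorted(blocks, key=lambda b: (b.q_start, b.target_id, b.t_start))


def read_index(targets: GenomeAssembly, k: int = 13) -> SeedIndex:
    """Index tuned for mapping short reads (k=13 vs the contig default 15)."""
    return SeedIndex(targets, k=k)


def paf_table(blocks: list[AlignmentBlock], q_len: int, t_lens: dict[str, int]) -> str:
    """PAF-like TSV debug dump of alignment blocks."""
    rows = []
    for b in blocks:
        rows.append("\t".join(map(str, [
            b.query_id, q_len, b.q_start, b.q_end, b.strand,
            b.target_id, t_lens[b.target_id], b.t_start, b.t_end,
            b.matches, b.aln_len,
        ])))
    return "\n".join(rows) + ("\n" if rows else "")
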