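"""Strain grouping of SAGs, chimeric-read cleaning, and co-assembly.

Single-cell amplified genomes from the same strain are identified by three
pairwise criteria (ANI > 95%, single-copy marker homology > 99%,
tetranucleotide correlation > 0.90) and connected into groups by single
linkage. Reads of grouped cells are cross-mapped to detect and split
amplification chimeras, then co-assembled into a composite SAG. Survivors of
a completeness/contamination filter are dereplicated into non-redundant SAGs
(nrSAGs), the binning references of the downstream steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import compare, pairwise
from .compare import MarkerSet, QualityReport
from .pairwise import SeedIndex
from .seqio import AssemblyKind, Contig, GenomeAssembly, ReadRecord

log = logging.getLogger(__name__)


@dataclass
class StrainGroup:
    """SAG ids connected by the three-criterion admission rule (single linkage)."""

    member_ids: list[str]
    evidence: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)


@dataclass
class ReadFragment:
    """A retained interval of one original read."""

    read_id: str
    start: int
    end: int
    seq: str


@dataclass
class CleanedReads:
    reads: list[ReadRecord]
    fragments: list[ReadFragment]
    split_log: dict[str, list[int]]


def select_sags(sags: list[tuple[GenomeAssembly, QualityReport]],
                completeness_min: float, contamination_max: float) -> list[GenomeAssembly]:
    """Keep SAGs with completeness strictly above and contamination strictly
    below the thresholds (a candidate sitting exactly on a threshold is out)."""
    if not 0 <= completeness_min <= 100:
        raise ValueError("completeness_min must be in [0, 100]")
    return [a for a, q in sags
            if q.completeness > completeness_min and q.contamination < contamination_max]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_strain_groups(sags: list[GenomeAssembly], markers: MarkerSet,
                        ani_min: float = 95.0, homology_min: float = 99.0,
                        tnf_min: float = 0.90) -> list[StrainGroup]:
    """Evaluate all unordered SAG pairs; connect pairs passing all three
    criteria; return connected components (singletons allowed).

    Undefined ANI (too few mapped fragments) and undefined marker homology
    (no shared marker) fail the respective criterion. The tetranucleotide
    correlation is evaluated first as a cheap gate; ANI and marker homology
    are only computed for pairs that pass it, which cannot change the result.
    """
    if not sags:
        raise ValueError("no SAGs to group")
    order = sorted(sags, key=lambda a: a.id)
    tnfs = {a.id: compare.tnf_vector(a) for a in order}
    indexes = {a.id: SeedIndex(a, k=15) for a in order}
    by_id = {a.id: a for a in order}
    uf = _UnionFind([a.id for a in order])
    evidence: dict[tuple[str, str], tuple[float, float, float]] = {}
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            corr = compare.tnf_correlation(tnfs[a.id], tnfs[b.id])
            if corr <= tnf_min:
                continue
            # query the smaller assembly so every fragment has a chance to map
            q, t = (a, b) if a.total_length <= b.total_length else (b, a)
            res = compare.ani(q, t, index=indexes[t.id])
            if not res.defined or res.ani <= ani_min:
                continue
            hom = compare.marker_homology(a, b, markers,
                                          index_a=indexes[a.id], index_b=indexes[b.id])
            if hom is None or hom <= homology_min:
                continue
            uf.union(a.id, b.id)
            evidence[(a.id, b.id)] = (res.ani, hom, corr)
    comps: dict[str, list[str]] = {}
    for a in order:
        comps.setdefault(uf.find(a.id), []).append(a.id)
    groups = []
    for root in sorted(comps):
        members = sorted(comps[root])
        ev = {k: v for k, v in evidence.items() if k[0] in members and k[1] in members}
        groups.append(StrainGroup(members, ev))
    del by_id
    return groups


def chimera_clean(group: StrainGroup,
                  reads_by_sag: dict[str, list[ReadRecord]],
                  sag_assemblies: dict[str, GenomeAssembly],
                  max_cycles: int = 3,
                  min_anchor: int = 30, min_fragment: int = 20,
                  full_cover: float = 0.9,
                  min_identity: float = 0.9) -> dict[str, CleanedReads]:
    """Cross-reference mapping and chimera splitting (ccSAG-style).

    Every read is mapped against the assemblies of all group members
    (including its own; a genuine read always maps full-length to its own
    assembly, so dropout boundaries in other members never trigger a split).
    A read whose best single mapping covers < ``full_cover`` of its length
    with an anchor of at least ``min_anchor`` bp is split at the mapped
    interval's boundaries; fragments shorter than ``min_fragment`` are
    discarded; newly produced flanking fragments are re-mapped in up to
    ``max_cycles`` cycles. Reads with no mapping anywhere are retained whole.
    """
    out: dict[str, CleanedReads] = {}
    members = [m for m in group.member_ids if m in sag_assemblies]
    indexes = {m: pairwise.read_index(sag_assemblies[m]) for m in members}
    for sag_id in group.member_ids:
        reads = reads_by_sag.get(sag_id)
        if reads is None:
            log.info("group member %s has no reads; contributes assembly only", sag_id)
            continue
        if len(group.member_ids) < 2:
            out[sag_id] = CleanedReads(
                reads, [ReadFragment(r.id, 0, len(r.seq), r.seq) for r in reads], {})
            continue
        targets = [indexes[m] for m in members]
        kept: list[ReadFragment] = []
        split_log: dict[str, list[int]] = {}
        work = [ReadFragment(r.id, 0, len(r.seq), r.seq) for r in reads]
        for _ in range(max_cycles):
            next_work: list[ReadFragment] = []
            for frag in work:
                rec = ReadRecord(frag.read_id, frag.seq)
                best = None
                for idx in targets:
                    for b in pairwise.map_read(rec, idx, min_frag=min_anchor,
                                               min_identity=min_identity):
                        if best is None or b.aln_len > best.aln_len:
                            best = b
                flen = len(frag.seq)
                if best is None:
                    kept.append(frag)  # no homology anywhere: retain whole
                    continue
                cover = (best.q_end - best.q_start) / flen
                if cover >= full_cover:
                    kept.append(frag)
                    continue
                # split into the aligned core and the unaligned flanks
                cuts = [c for c in (best.q_start, best.q_end) if 0 < c < flen]
                split_log.setdefault(frag.read_id, []).extend(frag.start + c for c in cuts)
                core = ReadFragment(frag.read_id, frag.start + best.q_start,
                                    frag.start + best.q_end,
                                    frag.seq[best.q_start:best.q_end])
                if len(core.seq) >= min_fragment:
                    kept.append(core)
                for s, e in ((0, best.q_start), (best.q_end, flen)):
                    if e - s >= min_fragment:
                        next_work.append(ReadFragment(frag.read_id, frag.start + s,
                                                      frag.start + e, frag.seq[s:e]))
            if not next_work:
                break
            work = next_work
        else:
            next_work = []
        kept.extend(next_work)  # cycle budget exhausted: keep as-is
        kept.sort(key=lambda f: (f.read_id, f.start))
        out[sag_id] = CleanedReads(
            [ReadRecord(f"{f.read_id}:{f.start}-{f.end}", f.seq) for f in kept],
            kept, split_log)
    return out


def _greedy_overlap_assemble(pieces: list[str], min_overlap: int = 40,
                             anchor: int = 40) -> list[str]:
    """Greedy longest-exact-suffix-prefix-overlap merging.

    Repeatedly merges the pair with the longest exact overlap >= min_overlap.
    Because a merge leaves its constituents' outer ends untouched, all useful
    overlaps can be enumerated between the original pieces once and consumed
    longest-first with a union-find over chains. Containments (overlap equal
    to a piece's full length) are not merged; exact duplicates are removed up
    front and contained leftovers fall to the length filter downstream.
    """
    uniq = sorted(set(p for p in pieces if len(p) >= anchor))
    short = [p for p in set(pieces) if len(p) < anchor]
    n = len(uniq)
    prefix: dict[str, list[int]] = {}
    for j, p in enumerate(uniq):
        prefix.setdefault(p[:anchor], []).append(j)
    edges: list[tuple[int, int, int]] = []  # (-overlap, i, j)
    for i, p in enumerate(uniq):
        li = len(p)
        found: set[int] = set()
        for pos in range(0, li - anchor + 1):
            ov = li - pos
            for j in prefix.get(p[pos:pos + anchor], ()):
                if j == i or j in found:
                    continue
                q = uniq[j]
                if ov >= len(q) or ov >= li:
                    continue  # containment/duplicate: not a chain edge
                if p[pos:] == q[:ov]:
                    found.add(j)
                    edges.append((-ov, i, j))
    edges.sort()
    head = list(range(n))   # head[rep] = first piece of the chain
    tail = list(range(n))   # tail[rep] = last piece of the chain
    rep = list(range(n))
    nxt: dict[int, tuple[int, int]] = {}

    def find(x: int) -> int:
        while rep[x] != x:
            rep[x] = rep[rep[x]]
            x = rep[x]
        return x

    for neg_ov, i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj or tail[ri] != i or head[rj] != j:
            continue
        nxt[i] = (j, -neg_ov)
        rep[rj] = ri
        tail[ri] = tail[rj]
    contigs = []
    for i in range(n):
        r = find(i)
        if head[r] != i:
            continue
        parts = [uniq[i]]
        cur = i
        while cur in nxt:
            cur, ov = nxt[cur]
            parts.append(uniq[cur][ov:])
        contigs.append("".join(parts))
    contigs.extend(short)
    return sorted(contigs, key=lambda s: (-len(s), s))


def coassemble(group: StrainGroup, cleaned: dict[str, CleanedReads],
               cosag_id: str, assembler=None, extra_pieces: list[str] | None = None,
               min_contig: int = 1000) -> GenomeAssembly:
    """Co-assemble the cleaned reads of a strain group into a composite SAG.

    ``assembler`` may be a callable ``(reads: list[str]) -> list[str]``
    wrapping an external assembler; by default the bundled greedy
    suffix-prefix overlap assembler is used. Pieces below ``min_contig`` bp
    are dropped from the result (the pipeline's contig floor).
    """
    pieces: list[str] = list(extra_pieces or [])
    for sag_id in group.member_ids:
        if sag_id in cleaned:
            pieces.extend(f.seq for f in cleaned[sag_id].fragments)
    if not pieces:
        raise ValueError(f"no reads available for group {group.member_ids}")
    if assembler is not None:
        contigs = assembler(pieces)
    else:
        contigs = _greedy_overlap_assemble(pieces)
    contigs = [c for c in contigs if len(c) >= min_contig]
    if not contigs:
        log.warning("co-assembly of %s produced no contig >= %d bp", cosag_id, min_contig)
    return GenomeAssembly(cosag_id,
                          [Contig(f"{cosag_id}_c{i:04d}", s) for i, s in enumerate(contigs)],
                          AssemblyKind.COSAG)


def make_nrsags(candidates: list[GenomeAssembly], markers: MarkerSet,
                completeness_min: float = 50.0, contamination_max: float = 10.0,
                dedup_ani: float = 99.5) -> list[GenomeAssembly]:
    """Quality-filter CoSAGs/singleton SAGs and dereplicate into nrSAGs.

    Keeps candidates with completeness > ``completeness_min`` and
    contamination < ``contamination_max``; among survivors at pairwise
    ANI >= ``dedup_ani`` only the most complete one is retained.
    """
    scored = []
    for a in sorted(candidates, key=lambda a: a.id):
        if not a.contigs:
            continue
        q = compare.estimate_quality(a, markers)
        if q.completeness > completeness_min and q.contamination < contamination_max:
            scored.append((a, q))
    # highest completeness first so the kept representative wins deterministically
    scored.sort(key=lambda t: (-t[1].completeness, t[0].id))
    kept: list[tuple[GenomeAssembly, SeedIndex]] = []
    out = []
    for a, q in scored:
        redundant = False
        idx_a = SeedIndex(a, k=15)
        for b, idx in kept:
            res = compare.ani(a, b, index=idx) if a.total_length <= b.total_length \
                else compare.ani(b, a, index=idx_a)
            if res.defined and res.ani >= dedup_ani:
                redundant = True
                log.info("nrSAG dedup: %s redundant with %s (ANI %.2f)", a.id, b.id, res.ani)
                break
        if not redundant:
            kept.append((a, idx_a))
            out.append(GenomeAssembly(a.id, a.contigs, AssemblyKind.NRSAG, dict(a.meta)))
    return sorted(out, key=lambda a: a.id)
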