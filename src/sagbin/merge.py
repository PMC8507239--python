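"""Guided merging of paired nrSAG and sgBin into a draft genome.

The more complete assembly becomes the primary; the secondary is filtered to
contigs >= 10 kb and folded in by a three-case rule: a secondary contig
contained in the primary is dropped, one overlapping a primary contig end by
>= 1 kb extends that contig with its non-overlapping tail, and one with no
qualifying alignment is appended. The result is labeled sgMAG when the sgBin
was primary and mgSAG when the nrSAG was. rRNA genes are counted by
alignment against class reference sequences with per-class length floors;
tRNA counts come from an external annotation table (no detector is bundled).
Draft quality tiers follow the Genomic Standards Consortium criteria.
"""

from __future__ import annotations

import logging
import pandas as pd

from . import compare, pairwise
from .compare import MarkerSet, QualityReport
from .pairwise import SeedIndex
from .seqio import AssemblyKind, Contig, GenomeAssembly, revcomp

log = logging.getLogger(__name__)

RRNA_MIN_ALN = {"5S": 80, "16S": 700, "23S": 1100}
_END_TOL = 100  # bp of slack when deciding that a block reaches a contig end


def choose_primary(nrsag: GenomeAssembly, sgbin: GenomeAssembly, markers: MarkerSet
                   ) -> tuple[GenomeAssembly, GenomeAssembly, str]:
    """Pick the more complete assembly as primary (tie: the nrSAG).

    Returns (primary, secondary, label) where label is ``mgSAG`` when the
    nrSAG leads and ``sgMAG`` when the sgBin does.
    """
    if not nrsag.contigs or not sgbin.contigs:
        raise ValueError("choose_primary requires two non-empty assemblies")
    c_nr = compare.estimate_quality(nrsag, markers).completeness
    c_sg = compare.estimate_quality(sgbin, markers).completeness
    if c_sg > c_nr:
        return sgbin, nrsag, "sgMAG"
    if c_sg == c_nr:
        log.info("completeness tie (%s vs %s): nrSAG primary", nrsag.id, sgbin.id)
    return nrsag, sgbin, "mgSAG"


def filter_secondary(secondary: GenomeAssembly, min_len: int = 10000) -> GenomeAssembly:
    """Remove secondary contigs strictly shorter than ``min_len`` (10 kb kept)."""
    kept = [c for c in secondary.contigs if len(c.seq) >= min_len]
    return GenomeAssembly(secondary.id, kept, secondary.kind, dict(secondary.meta))


def merge_assemblies(primary: GenomeAssembly, secondary: GenomeAssembly,
                     label: str = "mgSAG", min_identity: float = 0.99,
                     min_extension_overlap: int = 1000,
                     containment: float = 0.95, min_novel: int = 100) -> GenomeAssembly:
    """Overlap-guided merge of a filtered secondary into the primary.

    Per secondary contig: (a) contained in the primary (>= ``containment``
    of its length aligned and less than ``min_novel`` bp novel) -> dropped;
    (b) overlapping a primary contig end by >= ``min_extension_overlap`` ->
    that contig is extended with the unaligned overhang (small unique
    insertions such as rRNA operons are recovered this way even from
    mostly-aligned contigs); (c) no qualifying alignment -> appended as a
    new contig. A mostly-aligned contig that offers no end extension is
    dropped rather than appended, so aligned sequence is never duplicated.

    Never deletes primary sequence; idempotent (re-merging the same
    secondary changes nothing). Conflicting extensions at one primary end
    keep the longest overhang; the losers are appended unmodified.
    """
    kind = AssemblyKind.SGMAG if label == "sgMAG" else AssemblyKind.MGSAG
    if not secondary.contigs:
        return GenomeAssembly(primary.id, list(primary.contigs), kind, dict(primary.meta))
    idx = SeedIndex(primary, k=15)
    plen = {c.id: len(c.seq) for c in primary.contigs}
    # candidate extensions: (primary contig id, 'L'/'R') -> (overhang, seq, source)
    extensions: dict[tuple[str, str], tuple[int, str, str]] = {}
    appended: list[Contig] = []
    for sc in sorted(secondary.contigs, key=lambda c: c.id):
        blocks = pairwise.align(sc, idx, min_identity=min_identity, min_len=500)
        if not blocks:
            appended.append(sc)
            continue
        covered = _union_len([(b.q_start, b.q_end) for b in blocks])
        novel = len(sc.seq) - covered
        if covered >= containment * len(sc.seq) and novel < min_novel:
            continue  # contained in the primary: drop
        exts = _terminal_extensions(sc, blocks, plen, min_extension_overlap)
        if not exts:
            if covered < 0.5 * len(sc.seq):
                appended.append(sc)  # mostly novel: keep as a new contig
            else:
                log.info("merge: %s mostly aligned (%.0f%%) but offers no end "
                         "extension; dropped to avoid duplication",
                         sc.id, 100 * covered / len(sc.seq))
            continue
        for key, overhang_seq in exts:
            prev = extensions.get(key)
            if prev is not None:
                winner, loser = (sc.id, prev[2]) if len(overhang_seq) > prev[0] \
                    else (prev[2], sc.id)
                log.info("conflicting extensions at %s:%s; keeping %s over %s",
                         key[0], key[1], winner, loser)
                if winner == sc.id:
                    extensions[key] = (len(overhang_seq), overhang_seq, sc.id)
            else:
                extensions[key] = (len(overhang_seq), overhang_seq, sc.id)
    contigs = []
    for c in primary.contigs:
        seq = c.seq
        left = extensions.get((c.id, "L"))
        right = extensions.get((c.id, "R"))
        if left:
            seq = left[1] + seq
        if right:
            seq = seq + right[1]
        contigs.append(Contig(c.id, seq))
    contigs.extend(appended)
    return GenomeAssembly(primary.id, contigs, kind, dict(primary.meta))


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total, end = 0, -1
    for s, e in sorted(intervals):
        s = max(s, end)
        if e > s:
            total += e - s
            end = e
    return total


def _terminal_extensions(sc: Contig, blocks, plen: dict[str, int],
                         min_overlap: int):
    """All (primary end, overhang sequence) extensions offered by ``sc``.

    A block qualifies when it spans >= min_overlap, reaches a primary contig
    end (within a small tolerance) and the secondary contig runs past that
    end. The overhang is trimmed to the secondary's *unaligned* portion next
    to the block: sequence that also aligns elsewhere in the primary (e.g.
    the far side of a gap the secondary bridges) is already represented and
    must not be duplicated. A contig bridging a gap between two primary
    contigs offers the gap from both sides; each unaligned interval is
    claimed once (by the deterministically first candidate). Orientation is
    normalized to primary coordinates.
    """
    n = len(sc.seq)
    out = []
    claimed: set[tuple[int, int]] = set()
    for b in sorted(blocks, key=lambda b: (-b.aln_len, b.target_id, b.t_start)):
        if b.aln_len < min_overlap:
            continue
        L = plen[b.target_id]
        seq = sc.seq if b.strand == "+" else revcomp(sc.seq)
        flip = b.strand == "-"
        # all aligned intervals of sc, expressed in `seq` orientation
        ivs = sorted((n - x.q_end, n - x.q_start) if flip else (x.q_start, x.q_end)
                     for x in blocks)
        qs, qe = (n - b.q_end, n - b.q_start) if flip else (b.q_start, b.q_end)
        if b.t_end >= L - _END_TOL and qe < n:
            stop = min((s for s, _ in ivs if s >= qe), default=n)
            key, frag, iv = (b.target_id, "R"), seq[qe:stop], (qe, stop)
        elif b.t_start <= _END_TOL and qs > 0:
            start = max((e for _, e in ivs if e <= qs), default=0)
            key, frag, iv = (b.target_id, "L"), seq[start:qs], (start, qs)
        else:
            continue
        # normalize the claimed interval to original-orientation coordinates
        iv_orig = (n - iv[1], n - iv[0]) if flip else iv
        if frag and iv_orig not in claimed:
            claimed.add(iv_orig)
            out.append((key, frag))
    return out


def _parse_rrna_refs(rrna_refs) -> dict[str, list[str]]:
    """Accept a {class: [seq, ...]} mapping or a labeled GenomeAssembly whose
    record ids contain a 5S/16S/23S token."""
    if isinstance(rrna_refs, dict):
        return {k: (v if isinstance(v, list) else [v]) for k, v in rrna_refs.items()}
    classes: dict[str, list[str]] = {}
    for c in rrna_refs.contigs:
        for cls in RRNA_MIN_ALN:
            if cls in c.id:
                classes.setdefault(cls, []).append(c.seq)
                break
        else:
            raise ValueError(f"rRNA reference {c.id!r} has no 5S/16S/23S label")
    return classes


def count_rna_genes(assembly: GenomeAssembly, rrna_refs,
                    trna_annotation: pd.DataFrame | None = None,
                    min_identity: float = 0.9) -> tuple[dict[str, int], int]:
    """Count rRNA loci by reference alignment and tRNAs from an annotation.

    An rRNA copy is a non-overlapping locus aligning to a class reference at
    >= ``min_identity`` with aligned length >= the class floor (5S: 80 bp,
    16S: 700 bp, 23S: 1100 bp). tRNAs are read from ``trna_annotation``
    (columns contig, start, end, strand, type); without one the count is 0
    with a warning.
    """
    classes = _parse_rrna_refs(rrna_refs)
    counts: dict[str, int] = {}
    idx = SeedIndex(assembly, k=15) if assembly.contigs else None
    for cls in ("5S", "16S", "23S"):
        loci: list = []
        for i, seq in enumerate(classes.get(cls, [])):
            if idx is None:
                continue
            blocks = pairwise.align(Contig(f"{cls}_{i}", seq), idx,
                                    min_identity=min_identity,
                                    min_len=RRNA_MIN_ALN[cls])
            loci.extend(blocks)
        counts[cls] = len(pairwise._prune(loci))
    if trna_annotation is None:
        log.warning("no tRNA annotation provided for %s; tRNA count set to 0", assembly.id)
        return counts, 0
    required = {"contig", "start", "end", "strand", "type"}
    if not required <= set(trna_annotation.columns):
        raise ValueError(f"annotation missing columns {sorted(required - set(trna_annotation.columns))}")
    contig_ids = {c.id for c in assembly.contigs}
    trna = trna_annotation[(trna_annotation["type"] == "tRNA")
                           & trna_annotation["contig"].isin(contig_ids)]
    return counts, int(len(trna))


def classify_quality(report: QualityReport) -> str:
    """Genomic Standards Consortium tier: HQ needs >90% completeness, <5%
    contamination, all three rRNAs and >=18 tRNAs; MQ needs >=50% / <10%."""
    rrna = report.rrna_counts or {}
    if (report.completeness > 90 and report.contamination < 5
            and all(rrna.get(k, 0) >= 1 for k in ("5S", "16S", "23S"))
            and report.trna_count >= 18):
        return "HQ"
    if report.completeness >= 50 and report.contamination < 10:
        return "MQ"
    return "LQ"
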