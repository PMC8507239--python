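"""Guided binning: assign metagenome contigs to nrSAG-anchored bins.

Each metagenome-assembled (MA) contig is aligned against every nrSAG;
alignment blocks with identity > 0.99 over > 200 bp are the qualifying
evidence, and the contig goes to the nrSAG with the largest summed
qualifying aligned length (ties: higher mean identity, then lexicographic
nrSAG id). A contig with no qualifying evidence stays unbinned. Every contig
is assigned at most once; assignment partitions the MA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import pairwise
from .pairwise import AlignmentBlock, SeedIndex
from .seqio import AssemblyKind, GenomeAssembly

UNBINNED = "UNBINNED"


@dataclass
class BinAssignment:
    assignments: dict[str, str]  # MA contig id -> nrSAG id or UNBINNED
    evidence: dict[str, list[AlignmentBlock]] = field(default_factory=dict)
    per_bin_lengths: dict[str, int] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for cid in self.assignments:
            blocks = self.evidence.get(cid, [])
            tgt = self.assignments[cid]
            rel = [b for b in blocks if tgt != UNBINNED]
            aligned = sum(b.aln_len for b in rel)
            mean_id = (sum(b.identity * b.aln_len for b in rel) / aligned) if aligned else 0.0
            rows.append((cid, tgt, aligned, round(mean_id, 6)))
        return pd.DataFrame(rows, columns=["contig", "bin", "aligned_bp", "mean_identity"])


def assign_contigs(ma: GenomeAssembly, nrsags: list[GenomeAssembly],
                   min_identity: float = 0.99, min_len: int = 200) -> BinAssignment:
    """Winner-take-all assignment of MA contigs to nrSAGs.

    Comparisons are strict (> min_identity, > min_len), matching the
    extraction rule the bins are defined by. Qualifying blocks on multiple
    contigs of the same nrSAG are summed, so nrSAG fragmentation does not
    penalize assignment. Deterministic under input permutation.
    """
    if not ma.contigs:
        raise ValueError("empty MA assembly")
    if not nrsags:
        raise ValueError("no nrSAGs to bin against")
    nrsags = sorted(nrsags, key=lambda a: a.id)
    indexes = [(a.id, SeedIndex(a, k=15)) for a in nrsags]
    assignments: dict[str, str] = {}
    evidence: dict[str, list[AlignmentBlock]] = {}
    per_bin: dict[str, int] = {}
    for contig in ma.contigs:
        best_key = None
        best_bin = UNBINNED
        winning: list[AlignmentBlock] = []
        for nrsag_id, idx in indexes:
            if len(contig.seq) <= min_len:
                continue
            blocks = [b for b in pairwise.align(contig, idx, min_identity=min_identity,
                                                min_len=min_len + 1)
                      if b.identity > min_identity and b.aln_len > min_len]
            if not blocks:
                continue
            total = sum(b.aln_len for b in blocks)
            mean_id = sum(b.identity * b.aln_len for b in blocks) / total
            key = (total, mean_id)
            # lexicographically smallest id wins ties because ids are scanned sorted
            if best_key is None or key > best_key:
                best_key, best_bin, winning = key, nrsag_id, blocks
        assignments[contig.id] = best_bin
        if best_bin != UNBINNED:
            evidence[contig.id] = winning
            per_bin[best_bin] = per_bin.get(best_bin, 0) + len(contig.seq)
    return BinAssignment(assignments, evidence, per_bin)


def build_sgbins(ma: GenomeAssembly, assignment: BinAssignment) -> list[GenomeAssembly]:
    """One sgBin per nrSAG with at least one assigned contig."""
    members: dict[str, list] = {}
    for contig in ma.contigs:
        tgt = assignment.assignments[contig.id]
        if tgt != UNBINNED:
            members.setdefault(tgt, []).append(contig)
    return [GenomeAssembly(f"sgBin_{nrsag_id}", contigs, AssemblyKind.SGBIN,
                           {"nrsag": nrsag_id})
            for nrsag_id, contigs in sorted(members.items())]


def extract_unbinned(ma: GenomeAssembly, assignment: BinAssignment) -> GenomeAssembly:
    """Unbinned MA contigs, in MA order, for hand-off to conventional binners."""
    contigs = [c for c in ma.contigs if assignment.assignments[c.id] == UNBINNED]
    return GenomeAssembly(f"{ma.id}_unbinned", contigs, AssemblyKind.MA)
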