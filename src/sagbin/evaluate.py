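"""Scoring drafts and bin assignments against known references.

A draft is matched to the reference with the highest ANI, provided that ANI
reaches 99.5% (otherwise it stays unassigned). Genomic coverage L is the
draft-side aligned length against the assigned reference, so precision
L/len(draft) is structurally <= 1 and duplicated draft sequence depresses
recall L/len(reference), not precision. Community-level totals count the
lengths of contigs placed in a bin labeled with the wrong reference and of
contigs left unbinned despite having a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import compare, pairwise
from .binning import UNBINNED, BinAssignment
from .pairwise import SeedIndex
from .seqio import GenomeAssembly

UNASSIGNED = "UNASSIGNED"


@dataclass
class ReferenceSet:
    genomes: list[GenomeAssembly]

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genomes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference genome ids")
        self.genomes = sorted(self.genomes, key=lambda g: g.id)

    def __iter__(self):
        return iter(self.genomes)

    def get(self, gid: str) -> GenomeAssembly:
        for g in self.genomes:
            if g.id == gid:
                return g
        raise KeyError(gid)

    def is_plasmid(self, genome_id: str, contig_id: str) -> bool:
        return self.get(genome_id).meta.get(f"plasmid:{contig_id}") == "1"


@dataclass
class EvalResult:
    draft_id: str
    ref_id: str
    L: int
    precision: float
    recall: float
    f1: float


@dataclass
class CommunityEval:
    incorrectly_binned_bp: int
    unbinned_bp: int
    per_bin: list[EvalResult] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.draft_id, r.ref_id, r.L, round(r.precision, 6), round(r.recall, 6),
              round(r.f1, 6)) for r in self.per_bin],
            columns=["draft", "reference", "L_bp", "precision", "recall", "f1"])


def closest_reference(draft: GenomeAssembly, refs: ReferenceSet,
                      min_ani: float = 99.5,
                      indexes: dict[str, SeedIndex] | None = None) -> str:
    """Reference id with the highest ANI to the draft, requiring
    ANI >= ``min_ani``; otherwise UNASSIGNED. Ties break lexicographically."""
    if not refs.genomes:
        raise ValueError("empty reference set")
    best_id, best_ani = UNASSIGNED, float("-inf")
    for ref in refs:
        idx = indexes.get(ref.id) if indexes else None
        res = compare.ani(draft, ref, index=idx)
        if res.defined and res.ani > best_ani:
            best_id, best_ani = ref.id, res.ani
    if best_ani < min_ani:
        return UNASSIGNED
    return best_id


def genomic_coverage(draft: GenomeAssembly, ref: GenomeAssembly,
                     min_identity: float = 0.9, min_len: int = 100,
                     index: SeedIndex | None = None) -> int:
    """Draft-side aligned length L against the assigned reference.

    Per draft contig, aligned query intervals are unioned before summing, so
    overlapping blocks never double-count draft bases.
    """
    idx = index if index is not None else SeedIndex(ref, k=15)
    total = 0
    for c in draft.contigs:
        blocks = pairwise.align(c, idx, min_identity=min_identity, min_len=min_len)
        intervals, end = sorted((b.q_start, b.q_end) for b in blocks), -1
        for s, e in intervals:
            s = max(s, end)
            if e > s:
                total += e - s
                end = e
            end = max(end, e)
    return total


def precision_recall_f1(L: int, len_draft: int, len_ref: int) -> tuple[float, float, float]:
    """P = L/len(draft), R = L/len(reference), F1 = 2PR/(P+R) (0 when P+R=0)."""
    if len_draft <= 0 or len_ref <= 0:
        raise ValueError("assembly lengths must be positive")
    if L < 0 or L > len_draft:
        raise ValueError(f"coverage L={L} outside [0, {len_draft}]")
    p = L / len_draft
    r = L / len_ref
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def evaluate_draft(draft: GenomeAssembly, refs: ReferenceSet,
                   min_ani: float = 99.5,
                   indexes: dict[str, SeedIndex] | None = None) -> EvalResult:
    """Closest-reference assignment plus L/P/R/F1 for one draft genome."""
    ref_id = closest_reference(draft, refs, min_ani=min_ani, indexes=indexes)
    if ref_id == UNASSIGNED:
        return EvalResult(draft.id, UNASSIGNED, 0, 0.0, 0.0, 0.0)
    ref = refs.get(ref_id)
    idx = indexes.get(ref_id) if indexes else None
    L = genomic_coverage(draft, ref, index=idx)
    p, r, f1 = precision_recall_f1(L, draft.total_length, ref.total_length)
    return EvalResult(draft.id, ref_id, L, p, r, f1)


def binning_error_totals(assignment: BinAssignment, ma: GenomeAssembly,
                         truth: dict[str, str],
                         bin_labels: dict[str, str]) -> CommunityEval:
    """Community-level incorrectly-binned and unbinned totals (bp).

    ``truth`` maps every MA contig to its source reference; ``bin_labels``
    maps each bin (nrSAG id) to its closest reference (or UNASSIGNED, in
    which case all member contigs with a truth label count as incorrect).
    """
    incorrect = unbinned = 0
    for contig in ma.contigs:
        if contig.id not in truth:
            raise KeyError(f"contig {contig.id!r} missing from truth table")
        bin_id = assignment.assignments[contig.id]
        if bin_id == UNBINNED:
            unbinned += len(contig.seq)
        else:
            label = bin_labels.get(bin_id, UNASSIGNED)
            if label == UNASSIGNED or label != truth[contig.id]:
                incorrect += len(contig.seq)
    return CommunityEval(incorrect, unbinned)
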