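"""Genome-level similarity and quality statistics.

Four signals drive the pipeline's decisions: tetranucleotide composition
(strain grouping pre-evidence), fragment-based ANI (grouping, dereplication,
closest-reference assignment), single-copy marker homology (grouping), and a
marker-set completeness/contamination estimator that stands in for a
lineage-aware checker. The estimator consumes a user-suppliable
:class:`MarkerSet`; the synthetic community module fabricates one.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats

from . import pairwise
from .pairwise import SeedIndex, _cigar_stats, _encode, _kmer_codes
from .seqio import Contig, GenomeAssembly, revcomp

# canonical (reverse-complement collapsed) tetramer index: 256 codes -> 136 slots
_CANON = np.zeros(256, dtype=np.int64)


def _build_canon() -> None:
    canon_codes = []
    for code in range(256):
        b = [(code >> s) & 3 for s in (6, 4, 2, 0)]
        rcb = [3 - x for x in reversed(b)]
        rc_code = (rcb[0] << 6) | (rcb[1] << 4) | (rcb[2] << 2) | rcb[3]
        canon_codes.append(min(code, rc_code))
    uniq = sorted(set(canon_codes))
    slot = {c: i for i, c in enumerate(uniq)}
    for code in range(256):
        _CANON[code] = slot[canon_codes[code]]


_build_canon()
N_CANONICAL_TETRAMERS = int(_CANON.max()) + 1  # 136


@dataclass
class TnfVector:
    """Canonical tetranucleotide frequencies (136-dimensional, sums to 1)."""

    values: np.ndarray


@dataclass
class AniResult:
    """Fragment-based average nucleotide identity.

    ``ani`` is the mean identity (percent) over mapped fragments; it is only
    meaningful when enough fragments mapped (``defined``), mirroring the
    minimum-support behaviour of fragment-ANI tools.
    """

    ani: float
    frag_count: int
    frag_mapped: int
    defined: bool

    @property
    def aligned_fraction(self) -> float:
        return self.frag_mapped / self.frag_count if self.frag_count else 0.0


@dataclass
class MarkerSet:
    """Named DNA sequences expected to occur single-copy in every genome."""

    name: str
    markers: dict[str, str]

    def __post_init__(self) -> None:
        for mid, seq in self.markers.items():
            if len(seq) < 100:
                raise ValueError(f"marker {mid!r} shorter than 100 bp")


@dataclass
class QualityReport:
    completeness: float
    contamination: float
    rrna_counts: dict[str, int] | None = None
    trna_count: int = 0
    tier: str | None = None


def tnf_vector(assembly: GenomeAssembly) -> TnfVector:
    """Count every overlapping N-free tetramer across all contigs, collapse
    reverse complements, normalize to frequencies."""
    counts = np.zeros(N_CANONICAL_TETRAMERS, dtype=np.int64)
    for c in assembly.contigs:
        _, codes = _kmer_codes(_encode(c.seq), 4)
        if codes.size:
            counts += np.bincount(_CANON[codes.astype(np.int64)],
                                  minlength=N_CANONICAL_TETRAMERS)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"assembly {assembly.id!r}: no valid tetramers")
    return TnfVector(counts / total)


def tnf_correlation(a: TnfVector, b: TnfVector) -> float:
    """Pearson correlation of two tetranucleotide frequency vectors."""
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        raise ValueError("zero-variance TNF vector")
    return float(stats.pearsonr(a.values, b.values).statistic)


def _fragments(assembly: GenomeAssembly, frag_len: int) -> list[Contig]:
    """Consecutive frag_len windows per contig; terminal window kept if >= frag_len/2."""
    frags = []
    for c in assembly.contigs:
        n_full, rem = divmod(len(c.seq), frag_len)
        for i in range(n_full):
            frags.append(Contig(f"{c.id}|f{i}", c.seq[i * frag_len:(i + 1) * frag_len]))
        if rem >= frag_len / 2:
            frags.append(Contig(f"{c.id}|f{n_full}", c.seq[n_full * frag_len:]))
    return frags


def ani(query: GenomeAssembly, target: GenomeAssembly, frag_len: int = 3000,
        min_frag_identity: float = 0.8, min_support: int = 5,
        index: SeedIndex | None = None) -> AniResult:
    """Fragment-mean ANI of ``query`` against ``target``.

    The query is chopped into ``frag_len`` windows; each fragment's best
    alignment block with identity >= ``min_frag_identity`` counts it as
    mapped. ANI = 100 x mean identity over mapped fragments, undefined below
    ``min_support`` mapped fragments. A prebuilt ``index`` of the target may
    be passed to amortize indexing across many queries.
    """
    if not query.contigs or not target.contigs:
        raise ValueError("ani requires two non-empty assemblies")
    idx = index if index is not None else SeedIndex(target, k=15)
    frags = _fragments(query, frag_len)
    identities = []
    for f in frags:
        # a fragment counts as mapped when at least half of it aligns
        blocks = pairwise.align(f, idx, min_identity=min_frag_identity,
                                min_len=frag_len // 2)
        if blocks:
            identities.append(max(b.identity for b in blocks))
    mapped = len(identities)
    defined = mapped >= min_support
    value = 100.0 * float(np.mean(identities)) if mapped else float("nan")
    return AniResult(value, len(frags), mapped, defined)


def _best_marker_locus(marker_id: str, seq: str, idx: SeedIndex,
                       min_identity: float, min_cov: float):
    blocks = pairwise.align(Contig(marker_id, seq), idx, min_identity=min_identity,
                            min_len=max(100, int(min_cov * len(seq))))
    if not blocks:
        return None
    return max(blocks, key=lambda b: (b.identity * b.aln_len, b.target_id, -b.t_start))


def _extract(assembly: GenomeAssembly, block) -> str:
    seq = assembly.get(block.target_id).seq[block.t_start:block.t_end]
    return revcomp(seq) if block.strand == "-" else seq


def marker_homology(a: GenomeAssembly, b: GenomeAssembly, markers: MarkerSet,
                    min_identity: float = 0.8, min_cov: float = 0.5,
                    index_a: SeedIndex | None = None,
                    index_b: SeedIndex | None = None) -> float | None:
    """Mean percent identity between the copies of shared single-copy markers.

    A marker is shared when it is locatable in both assemblies at
    >=``min_identity`` over >=``min_cov`` of its length. Returns None
    (criterion treated as failed) when no marker is shared.
    """
    if not markers.markers:
        raise ValueError("empty marker set")
    ia = index_a if index_a is not None else SeedIndex(a, k=15)
    ib = index_b if index_b is not None else SeedIndex(b, k=15)
    idents = []
    for mid, seq in markers.markers.items():
        ba = _best_marker_locus(mid, seq, ia, min_identity, min_cov)
        bb = _best_marker_locus(mid, seq, ib, min_identity, min_cov)
        if ba is None or bb is None:
            continue
        sa, sb = _extract(a, ba), _extract(b, bb)
        if len(sa) > len(sb):
            sa, sb = sb, sa
        # infix alignment: a copy truncated at an assembly gap is compared
        # over its aligned span, not penalized for the missing remainder
        res = edlib.align(sa, sb, mode="HW", task="path")
        matches, columns = _cigar_stats(res["cigar"])
        if columns:
            idents.append(matches / columns)
    if not idents:
        return None
    return 100.0 * float(np.mean(idents))


def marker_loci(assembly: GenomeAssembly, markers: MarkerSet,
                min_identity: float = 0.8, min_cov: float = 0.5,
                index: SeedIndex | None = None) -> dict[str, int]:
    """Distinct non-overlapping locus count per marker (copy number)."""
    idx = index if index is not None else SeedIndex(assembly, k=15)
    copies: dict[str, int] = {}
    for mid, seq in markers.markers.items():
        blocks = pairwise.align(Contig(mid, seq), idx, min_identity=min_identity,
                                min_len=max(100, int(min_cov * len(seq))))
        # align() already prunes to non-overlapping target loci
        copies[mid] = len(blocks)
    return copies


def estimate_quality(assembly: GenomeAssembly, markers: MarkerSet,
                     index: SeedIndex | None = None) -> QualityReport:
    """Marker-set completeness/contamination estimate.

    completeness = 100 x fraction of markers found at least once;
    contamination = 100 x (sum over markers of extra copies) / marker count.
    """
    if not markers.markers:
        raise ValueError("empty marker set")
    if not assembly.contigs:
        return QualityReport(0.0, 0.0)
    copies = marker_loci(assembly, markers, index=index)
    n = len(markers.markers)
    found = sum(1 for c in copies.values() if c >= 1)
    extra = sum(max(0, c - 1) for c in copies.values())
    return QualityReport(100.0 * found / n, 100.0 * extra / n)
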