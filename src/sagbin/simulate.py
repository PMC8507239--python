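"""Deterministic synthetic mock community generator.

Emulates the inputs the guided-binning workflow consumes, with full truth
labels, so every stage is testable without sequencing data: reference
chromosomes at sampled GC with implanted single-copy marker genes and rRNA
tokens, strain pairs at a chosen divergence carrying strain-specific
plasmids, SAG assemblies with window-wise amplification dropout, single-cell
reads with junction chimeras, and fragmented metagenome contigs.

All randomness flows through a single integer seed; identical spec + seed
yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import MarkerSet
from .evaluate import ReferenceSet
from .seqio import AssemblyKind, Contig, GenomeAssembly, ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# synthetic rRNA tokens use realistic gene lengths (5S/16S/23S)
RRNA_TOKEN_LENS = {"5S": 120, "16S": 1550, "23S": 2900}


@dataclass
class CommunitySpec:
    """Layout of the synthetic community.

    The defaults describe the study conditions the pipeline is exercised
    under: ten species of 200 kb with GC drawn in [0.3, 0.7], one
    high-identity strain pair (1.5% divergence, ~98.5% ANI) whose strains
    carry one unique plasmid each, and 40 implanted 1 kb single-copy
    markers. Marker sequences diverge 3% between species but are implanted
    verbatim in both strains of a pair unless ``marker_snp_rate`` is set.
    """

    n_species: int = 10
    genome_len: int = 200_000
    gc_range: tuple[float, float] = (0.3, 0.7)
    strain_pairs: list[tuple[int, float, tuple[int, ...]]] = field(
        default_factory=lambda: [(0, 0.015, (30_000, 25_000))])
    marker_count: int = 40
    marker_len: int = 1000
    marker_divergence: float = 0.03
    marker_snp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for _, div, _ in self.strain_pairs:
            if not 0 < div <= 0.05:
                raise ValueError(f"strain divergence {div} outside (0, 0.05]")


@dataclass
class SagSimSpec:
    """Single-cell amplification artifact model: window-wise dropout to a
    target completeness, tiled reads at a fold depth, and a fraction of
    junction-chimeric reads (the signature MDA artifact)."""

    completeness_target: float = 0.7
    read_len: int = 150
    depth: int = 3
    chimera_rate: float = 0.0
    dropout_window: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.completeness_target <= 1:
            raise ValueError("completeness_target must be in (0, 1]")
        if not 0 <= self.chimera_rate <= 0.2:
            raise ValueError("chimera_rate must be in [0, 0.2]")


@dataclass
class SyntheticCommunity:
    refs: ReferenceSet
    markers: MarkerSet
    rrna_refs: dict[str, list[str]]
    truth: pd.DataFrame          # contig id, genome id, is_plasmid
    implants: pd.DataFrame       # genome id, contig id, element, start, end
    pair_partners: dict[str, str]
    variant_positions: dict[str, np.ndarray]  # strain-B genome id -> substituted sites


@dataclass
class SagSimResult:
    assembly: GenomeAssembly
    reads: list[ReadRecord]
    chimera_truth: pd.DataFrame  # read id, junction (position within read)
    retained: dict[str, list[tuple[int, int]]]  # source contig -> kept intervals


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc, p_at = gc / 2, (1 - gc) / 2
    arr = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return arr.tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protect: list[tuple[int, int]] | None = None) -> tuple[str, np.ndarray]:
    """Uniform substitutions at ``rate``, never placing the original base;
    intervals in ``protect`` are left untouched. Returns the substituted
    sequence and the substituted positions."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if protect:
        for s, e in protect:
            hit[s:e] = False
    pos = np.flatnonzero(hit)
    code = {65: 0, 67: 1, 71: 2, 84: 3}
    enc = np.full(256, -1, np.int8)
    for b, v in code.items():
        enc[b] = v
    cur = enc[arr[pos]]
    shift = rng.integers(1, 4, size=pos.size)
    arr[pos] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode(), pos


def _mutate_within(rng: np.random.Generator, seq: str, rate: float,
                   intervals: list[tuple[int, int]]) -> tuple[str, np.ndarray]:
    """Substitutions at ``rate`` restricted to the given intervals."""
    inside = np.zeros(len(seq), dtype=bool)
    for s, e in intervals:
        inside[s:e] = True
    mutated, pos = _mutate(rng, seq, rate, protect=_runs(~inside))
    return mutated, pos


def _place_nonoverlapping(rng: np.random.Generator, genome_len: int,
                          lengths: list[int], margin: int = 200) -> list[int]:
    """Random non-overlapping start positions for elements of given lengths."""
    need = sum(lengths) + margin * len(lengths)
    free = genome_len - need
    if free <= 0:
        raise ValueError("implanted elements do not fit in the genome")
    gaps = rng.multinomial(free, np.full(len(lengths) + 1, 1 / (len(lengths) + 1)))
    starts, cursor = [], 0
    for i, L in enumerate(lengths):
        cursor += gaps[i] + margin // 2
        starts.append(cursor)
        cursor += L + margin // 2
    return starts


def generate_references(spec: CommunitySpec) -> SyntheticCommunity:
    """References, marker set, rRNA tokens and complete truth tables."""
    rng = np.random.default_rng(spec.seed)
    canonical = {f"marker_{i:03d}": _random_seq(rng, spec.marker_len)
                 for i in range(spec.marker_count)}
    # rRNA tokens are highly conserved but not identical across species;
    # per-species variants diverge like markers, strain pairs share verbatim
    rrna = {cls: [_random_seq(rng, L)] for cls, L in RRNA_TOKEN_LENS.items()}
    pair_of = {si: (div, plasmids) for si, div, plasmids in spec.strain_pairs}
    genomes, truth_rows, implant_rows = [], [], []
    pair_partners: dict[str, str] = {}
    variant_positions: dict[str, np.ndarray] = {}
    for si in range(spec.n_species):
        gc = float(rng.uniform(*spec.gc_range))
        chrom = _random_seq(rng, spec.genome_len, gc)
        elements = [(mid, _mutate(rng, seq, spec.marker_divergence)[0])
                    for mid, seq in canonical.items()]
        elements += [(cls, _mutate(rng, rrna[cls][0], spec.marker_divergence)[0])
                     for cls in ("5S", "16S", "23S")]
        starts = _place_nonoverlapping(rng, spec.genome_len, [len(s) for _, s in elements])
        arr = list(chrom)
        protect = []
        for (eid, eseq), s in zip(elements, starts):
            arr[s:s + len(eseq)] = eseq
            protect.append((s, s + len(eseq)))
        chrom = "".join(arr)
        gid = f"ref_s{si:02d}"
        if si in pair_of:
            div, plasmid_lens = pair_of[si]
            gid_a, gid_b = f"{gid}a", f"{gid}b"
            # implanted elements stay verbatim between strains unless a marker
            # SNP rate is requested to exercise the homology criterion; the
            # substitution rate outside them is scaled so the genome-wide
            # divergence always matches the requested value
            prot_len = sum(e - s for s, e in protect)
            marker_prot = sum(e - s for s, e in protect[:spec.marker_count])
            want = div * len(chrom) - spec.marker_snp_rate * marker_prot
            eff = max(0.0, want) / max(1, len(chrom) - prot_len)
            chrom_b, pos = _mutate(rng, chrom, eff, protect=protect)
            if spec.marker_snp_rate > 0:
                chrom_b, pos2 = _mutate_within(rng, chrom_b, spec.marker_snp_rate,
                                               protect[:spec.marker_count])
                pos = np.union1d(pos, pos2)
            strains = [(gid_a, chrom), (gid_b, chrom_b)]
            variant_positions[gid_b] = pos
            pair_partners[gid_a], pair_partners[gid_b] = gid_b, gid_a
            for (sgid, cseq), pl_len in zip(strains, plasmid_lens):
                contigs = [Contig(f"{sgid}_chrom", cseq)]
                meta = {}
                if pl_len:
                    pl = _random_seq(rng, pl_len, gc)
                    contigs.append(Contig(f"{sgid}_plasmid", pl))
                    meta[f"plasmid:{sgid}_plasmid"] = "1"
                genomes.append(GenomeAssembly(sgid, contigs, AssemblyKind.REFERENCE, meta))
                for c in contigs:
                    truth_rows.append((c.id, sgid, int(c.id.endswith("plasmid"))))
                for (eid, eseq), s in zip(elements, starts):
                    implant_rows.append((sgid, f"{sgid}_chrom", eid, s, s + len(eseq)))
        else:
            genomes.append(GenomeAssembly(
                gid, [Contig(f"{gid}_chrom", chrom)], AssemblyKind.REFERENCE))
            truth_rows.append((f"{gid}_chrom", gid, 0))
            for (eid, eseq), s in zip(elements, starts):
                implant_rows.append((gid, f"{gid}_chrom", eid, s, s + len(eseq)))
    truth = pd.DataFrame(truth_rows, columns=["contig", "genome", "is_plasmid"])
    implants = pd.DataFrame(implant_rows,
                            columns=["genome", "contig", "element", "start", "end"])
    return SyntheticCommunity(ReferenceSet(genomes), MarkerSet("synthetic", canonical),
                              rrna, truth, implants, pair_partners, variant_positions)


def _dropout_intervals(rng: np.random.Generator, length: int, target: float,
                       window: int) -> list[tuple[int, int]]:
    """Retained intervals after deleting random windows down to ``target``.

    Window starts are drawn as a shuffled grid and consumed until the
    retained fraction reaches the target, so lowering the target with the
    same generator state removes a superset of windows (used by
    :func:`nested_dropout_series`).
    """
    keep = np.ones(length, dtype=bool)
    if target >= 1.0:
        return [(0, length)]
    starts = rng.permutation(np.arange(0, max(1, length - window), window // 2))
    for s in starts:
        if keep.mean() <= target:
            break
        keep[s:s + window] = False
    return _runs(keep)


def _runs(keep: np.ndarray) -> list[tuple[int, int]]:
    padded = np.r_[False, keep, False]
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def simulate_sag(genome: GenomeAssembly, spec: SagSimSpec, sag_id: str | None = None
                 ) -> SagSimResult:
    """A SAG assembly plus its single-cell reads for one genome.

    Dropout removes random windows until the retained fraction reaches the
    completeness target; the assembly is the retained segments (>= 1 kb).
    Reads tile the retained segments at the requested depth; a
    ``chimera_rate`` fraction are junction-joins of two random retained loci
    with the junction position recorded in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    sid = sag_id or f"sag_{genome.id}"
    retained: dict[str, list[tuple[int, int]]] = {}
    segments: list[tuple[str, int, str]] = []
    # single global dropout budget across contigs, applied per contig
    for c in genome.contigs:
        ivs = _dropout_intervals(rng, len(c.seq), spec.completeness_target,
                                 spec.dropout_window)
        retained[c.id] = ivs
        for s, e in ivs:
            segments.append((c.id, s, c.seq[s:e]))
    contigs = [Contig(f"{sid}_c{i:04d}", seq, origin=f"{cid}:{s}")
               for i, (cid, s, seq) in enumerate(segments) if len(seq) >= 1000]
    assembly = GenomeAssembly(sid, contigs, AssemblyKind.SAG,
                              {"source": genome.id})
    reads: list[ReadRecord] = []
    raw: list[str] = []
    rl = spec.read_len
    stride = max(1, rl // spec.depth)
    for cid, s0, seq in segments:
        if len(seq) < rl:
            continue
        offsets = list(range(0, len(seq) - rl + 1, stride))
        if offsets[-1] != len(seq) - rl:
            offsets.append(len(seq) - rl)
        raw.extend(seq[o:o + rl] for o in offsets)
    pool = [seq for _, _, seq in segments if len(seq) >= rl]
    chim_rows = []
    n_chim = int(round(spec.chimera_rate * len(raw)))
    chim_idx = set(rng.choice(len(raw), size=n_chim, replace=False).tolist()) if n_chim else set()
    for i, seq in enumerate(raw):
        rid = f"{sid}_r{i:06d}"
        if i in chim_idx:
            j = int(rng.integers(30, rl - 29))
            src = pool[int(rng.integers(len(pool)))]
            pos = int(rng.integers(0, len(src) - (rl - j) + 1))
            seq = seq[:j] + src[pos:pos + rl - j]
            chim_rows.append((rid, j))
        reads.append(ReadRecord(rid, seq))
    chim = pd.DataFrame(chim_rows, columns=["read", "junction"])
    return SagSimResult(assembly, reads, chim, retained)


def nested_dropout_series(genome: GenomeAssembly, targets: list[float],
                          window: int, seed: int) -> list[GenomeAssembly]:
    """SAG-like assemblies at several completeness targets whose retained
    regions are nested (higher completeness is a superset), for monotonicity
    experiments."""
    out = []
    for t in sorted(targets, reverse=True):
        spec = SagSimSpec(completeness_target=t, dropout_window=window, seed=seed)
        sim = simulate_sag(genome, spec, sag_id=f"sag_{genome.id}_c{int(round(t * 100))}")
        out.append(sim.assembly)
    return out


def simulate_metagenome(community: SyntheticCommunity,
                        abundances: dict[str, float] | None = None,
                        frag_mean: int = 20_000, seed: int = 0,
                        consensus_rate: float = 0.0,
                        ma_id: str = "ma") -> tuple[GenomeAssembly, dict[str, str]]:
    """Fragment the references into metagenome-style contigs with truth labels.

    Fragment lengths are drawn around ``frag_mean`` (floor 1 kb); genomes
    with abundance below the maximum lose a matching fraction of random
    fragments. With ``consensus_rate`` > 0, that fraction of strain-pair
    contigs has its variant sites randomly mixed with the partner strain
    (population-consensus artifact for stress tests).
    """
    rng = np.random.default_rng(seed)
    refs = community.refs
    ab = abundances or {g.id: 1.0 for g in refs}
    if any(v <= 0 for v in ab.values()):
        raise ValueError("abundances must be positive")
    amax = max(ab.values())
    contigs, truth = [], {}
    n = 0
    for g in refs:
        partner = community.pair_partners.get(g.id)
        for c in g.contigs:
            cuts, pos = [], 0
            while pos < len(c.seq):
                L = int(rng.normal(frag_mean, frag_mean / 4))
                L = max(1000, L)
                if len(c.seq) - (pos + L) < 1000:
                    L = len(c.seq) - pos
                cuts.append((pos, pos + L))
                pos += L
            for s, e in cuts:
                if rng.random() > ab[g.id] / amax:
                    continue  # low-abundance genome loses this fragment
                seq = c.seq[s:e]
                if (partner and consensus_rate > 0 and not c.id.endswith("plasmid")
                        and rng.random() < consensus_rate):
                    seq = _mix_variants(rng, seq, s, e, g.id, partner, community)
                cid = f"{ma_id}_{n:05d}"
                n += 1
                contigs.append(Contig(cid, seq, origin=f"{c.id}:{s}"))
                truth[cid] = g.id
    return GenomeAssembly(ma_id, contigs, AssemblyKind.MA), truth


def _mix_variants(rng: np.random.Generator, seq: str, s: int, e: int,
                  gid: str, partner: str, community: SyntheticCommunity) -> str:
    """Randomly flip half of the strain-discriminating sites in a fragment to
    the partner strain's allele."""
    b_id = gid if gid in community.variant_positions else partner
    var = community.variant_positions.get(b_id)
    if var is None:
        return seq
    local = var[(var >= s) & (var < e)] - s
    if local.size == 0:
        return seq
    flip = local[rng.random(local.size) < 0.5]
    partner_chrom = community.refs.get(partner).contigs[0].seq
    arr = list(seq)
    for p in flip:
        arr[p] = partner_chrom[s + p]
    return "".join(arr)
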