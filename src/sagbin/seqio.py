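"""Sequence containers, FASTA/FASTQ I/O and basic assembly statistics.

The toolkit moves genome assemblies between several roles (single-cell
amplified genomes, co-assemblies, metagenome contigs, guided bins, merged
drafts, references). All of them share one container, :class:`GenomeAssembly`,
tagged with an :class:`AssemblyKind`. Coordinates are 0-based, half-open
throughout the package.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID = set("ACGTN")


class AssemblyKind(str, Enum):
    """Role of an assembly in the guided-binning workflow."""

    SAG = "SAG"
    COSAG = "CoSAG"
    NRSAG = "nrSAG"
    MA = "MA"
    SGBIN = "sgBin"
    SGMAG = "sgMAG"
    MGSAG = "mgSAG"
    REFERENCE = "REFERENCE"


def _normalize_seq(seq: str, name: str) -> str:
    """Uppercase and collapse non-ACGTN characters (IUPAC ambiguity codes) to N."""
    s = seq.upper()
    if not set(s) <= _VALID:
        n_bad = sum(c not in _VALID for c in s)
        log.warning("%s: %d non-ACGTN character(s) mapped to N", name, n_bad)
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


@dataclass
class Contig:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        self.seq = _normalize_seq(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    """An ordered collection of contigs with a workflow role tag.

    ``meta`` carries free-form per-assembly annotation; the synthetic
    community generator uses it to flag plasmid contigs on references
    (``meta["plasmid:<contig_id>"] = "1"``).
    """

    id: str
    contigs: list[Contig]
    kind: AssemblyKind
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate contig id {i!r} in assembly {self.id!r}")
                seen.add(i)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass
class ReadRecord:
    """A sequencing read; quality scores are carried but never interpreted."""

    id: str
    seq: str
    mate: int | None = None
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        self.seq = _normalize_seq(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AssemblyStats:
    total_length: int
    n_contigs: int
    n50: int
    max_contig: int
    gc: float


def read_fasta(path: str | Path, kind: AssemblyKind = AssemblyKind.SAG,
               assembly_id: str | None = None) -> GenomeAssembly:
    """Read a multi-record FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased; ambiguity codes become N (with a warning).
    Raises on a missing or empty file and on duplicate record ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs = [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeAssembly(assembly_id or path.stem, contigs, kind)


def write_fasta(assembly: GenomeAssembly, path: str | Path, wrap: int = 60) -> None:
    """Write an assembly as wrapped FASTA. Round-trips ids and sequences exactly."""
    if not assembly.contigs:
        raise ValueError(f"assembly {assembly.id!r} is empty; refusing to write")
    path = Path(path)
    with open(path, "w") as fh:
        for c in assembly.contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), wrap):
                fh.write(c.seq[i:i + wrap] + "\n")


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read FASTQ (gz-transparent). Mate number parsed from a ``/1``/``/2`` suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reads: list[ReadRecord] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            rid, mate = rec.id, None
            if rid.endswith("/1") or rid.endswith("/2"):
                mate = int(rid[-1])
                rid = rid[:-2]
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(ReadRecord(rid, str(rec.seq), mate=mate, quality=qual))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.seq)
            rid = r.id if r.mate is None else f"{r.id}/{r.mate}"
            fh.write(f"@{rid}\n{r.seq}\n+\n{qual}\n")


def assembly_stats(assembly: GenomeAssembly) -> AssemblyStats:
    """Total length, contig count, N50, longest contig, GC fraction.

    N50 is the length of the shortest contig in the minimal set of longest
    contigs whose summed length reaches half the total.
    """
    if not assembly.contigs:
        raise ValueError("assembly_stats requires at least one contig")
    lengths = np.sort(np.array([len(c) for c in assembly.contigs]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[int(np.searchsorted(cum, total / 2))])
    gc_bases = sum(c.seq.count("G") + c.seq.count("C") for c in assembly.contigs)
    acgt = sum(len(c) - c.seq.count("N") for c in assembly.contigs)
    gc = gc_bases / acgt if acgt else 0.0
    return AssemblyStats(total, len(lengths), n50, int(lengths[0]), gc)


def filter_min_length(assembly: GenomeAssembly, min_len: int) -> GenomeAssembly:
    """Drop contigs shorter than ``min_len`` (order preserved, idempotent)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [c for c in assembly.contigs if len(c) >= min_len]
    if not kept and assembly.contigs:
        log.warning("assembly %s: all %d contigs shorter than %d bp",
                    assembly.id, len(assembly.contigs), min_len)
    return GenomeAssembly(assembly.id, kept, assembly.kind, dict(assembly.meta))


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")
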