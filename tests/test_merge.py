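"""Guided merging, rRNA counting and quality tiers."""

import pandas as pd
import pytest

from tests.conftest import make_assembly, random_seq
from sagbin import simulate
from sagbin.compare import QualityReport
from sagbin.merge import (choose_primary, classify_quality, count_rna_genes,
                          filter_secondary, merge_assemblies)
from sagbin.seqio import AssemblyKind, Contig, GenomeAssembly, revcomp


@pytest.fixture(scope="module")
def marked():
    spec = simulate.CommunitySpec(n_species=1, genome_len=50_000, strain_pairs=[],
                                  marker_count=20, seed=91)
    com = simulate.generate_references(spec)
    return com.refs.get("ref_s00").contigs[0].seq, com


class TestChoosePrimary:
    def test_more_complete_nrsag_gives_mgsag(self, marked):
        seq, com = marked
        nrsag = make_assembly({"c": seq[:40_000]}, AssemblyKind.NRSAG, aid="nr")
        sgbin = make_assembly({"c": seq[:25_000]}, AssemblyKind.SGBIN, aid="sg")
        p, s, label = choose_primary(nrsag, sgbin, com.markers)
        assert (p.id, s.id, label) == ("nr", "sg", "mgSAG")

    def test_more_complete_sgbin_gives_sgmag(self, marked):
        seq, com = marked
        nrsag = make_assembly({"c": seq[:20_000]}, AssemblyKind.NRSAG, aid="nr")
        sgbin = make_assembly({"c": seq}, AssemblyKind.SGBIN, aid="sg")
        p, s, label = choose_primary(nrsag, sgbin, com.markers)
        assert (p.id, label) == ("sg", "sgMAG")

    def test_tie_prefers_nrsag(self, marked):
        seq, com = marked
        nrsag = make_assembly({"c": seq}, AssemblyKind.NRSAG, aid="nr")
        sgbin = make_assembly({"c": seq}, AssemblyKind.SGBIN, aid="sg")
        p, _, label = choose_primary(nrsag, sgbin, com.markers)
        assert (p.id, label) == ("nr", "mgSAG")


class TestFilterSecondary:
    def test_10kb_boundary(self):
        asm = GenomeAssembly("s", [Contig("short", "A" * 9999),
                                   Contig("keep", "A" * 10_000)], AssemblyKind.SGBIN)
        out = filter_secondary(asm)
        assert [c.id for c in out.contigs] == ["keep"]

    def test_empty_result_merge_returns_primary(self):
        genome = random_seq(92, 30_000)
        primary = make_assembly({"p": genome}, AssemblyKind.NRSAG, aid="p")
        sec = filter_secondary(make_assembly({"s": genome[:5000]},
                                             AssemblyKind.SGBIN, aid="s"))
        merged = merge_assemblies(primary, sec)
        assert [c.seq for c in merged.contigs] == [genome]


class TestMergeAssemblies:
    def test_containment_dropped(self):
        genome = random_seq(93, 60_000)
        primary = make_assembly({"p": genome}, AssemblyKind.NRSAG, aid="p")
        sec = make_assembly({"s": genome[10_000:30_000]}, AssemblyKind.SGBIN, aid="s")
        merged = merge_assemblies(primary, sec)
        assert merged.total_length == 60_000 and len(merged.contigs) == 1

    def test_novel_contig_appended(self):
        genome = random_seq(94, 110_000)
        primary = make_assembly({"p": genome[:60_000]}, AssemblyKind.NRSAG, aid="p")
        sec = make_assembly({"s": genome[60_000:110_000]}, AssemblyKind.SGBIN, aid="s")
        merged = merge_assemblies(primary, sec)
        assert merged.total_length == 60_000 + 50_000
        assert len(merged.contigs) == 2

    @pytest.mark.parametrize("rc", [False, True])
    def test_terminal_extension(self, rc):
        genome = random_seq(95, 90_000)
        primary = make_assembly({"p": genome[:60_000]}, AssemblyKind.NRSAG, aid="p")
        tail = genome[58_000:90_000]  # 2 kb overlap + 30 kb novel tail
        sec = make_assembly({"s": revcomp(tail) if rc else tail},
                            AssemblyKind.SGBIN, aid="s")
        merged = merge_assemblies(primary, sec)
        assert len(merged.contigs) == 1
        assert merged.contigs[0].seq == genome[:90_000]

    def test_never_deletes_primary_and_idempotent(self):
        genome = random_seq(96, 80_000)
        primary = make_assembly({"p1": genome[:30_000], "p2": genome[40_000:60_000]},
                                AssemblyKind.NRSAG, aid="p")
        sec = make_assembly({"s1": genome[28_000:45_000], "s2": genome[60_000:80_000]},
                            AssemblyKind.SGBIN, aid="s")
        merged = merge_assemblies(primary, sec)
        assert merged.total_length >= primary.total_length
        again = merge_assemblies(merged, sec, label="mgSAG")
        assert [(c.id, c.seq) for c in again.contigs] == \
               [(c.id, c.seq) for c in merged.contigs]


@pytest.fixture(scope="module")
def rrna_tokens():
    return {cls: [random_seq(200 + i, L)]
            for i, (cls, L) in enumerate(simulate.RRNA_TOKEN_LENS.items())}


class TestCountRnaGenes:
    def test_full_16s_counted(self, rrna_tokens):
        backbone = random_seq(97, 10_000)
        asm = make_assembly({"c": backbone + rrna_tokens["16S"][0]})
        counts, _ = count_rna_genes(asm, rrna_tokens)
        assert counts["16S"] == 1

    def test_650bp_16s_fragment_rejected(self, rrna_tokens):
        asm = make_assembly({"c": random_seq(98, 10_000) + rrna_tokens["16S"][0][:650]})
        counts, _ = count_rna_genes(asm, rrna_tokens)
        assert counts["16S"] == 0

    def test_two_disjoint_23s_copies(self, rrna_tokens):
        spacer = random_seq(99, 5000)
        tok = rrna_tokens["23S"][0]
        asm = make_assembly({"c": tok + spacer + tok})
        counts, _ = count_rna_genes(asm, rrna_tokens)
        assert counts["23S"] == 2

    def test_trna_from_annotation(self, rrna_tokens):
        asm = make_assembly({"c": random_seq(100, 5000)})
        annot = pd.DataFrame({"contig": ["c"] * 20 + ["other"],
                              "start": range(21), "end": range(1, 22),
                              "strand": ["+"] * 21,
                              "type": ["tRNA"] * 20 + ["tRNA"]})
        _, trna = count_rna_genes(asm, rrna_tokens, annot)
        assert trna == 20

    def test_malformed_annotation_errors(self, rrna_tokens):
        asm = make_assembly({"c": random_seq(101, 5000)})
        with pytest.raises(ValueError, match="columns"):
            count_rna_genes(asm, rrna_tokens, pd.DataFrame({"contig": ["c"]}))


class TestClassifyQuality:
    @pytest.mark.parametrize("comp,cont,rrna,trna,tier", [
        (95, 2, {"5S": 1, "16S": 1, "23S": 1}, 20, "HQ"),
        (95, 2, {"5S": 1, "16S": 0, "23S": 1}, 20, "MQ"),
        (49, 1, {"5S": 1, "16S": 1, "23S": 1}, 20, "LQ"),
        (91, 4.9, {"5S": 2, "16S": 1, "23S": 1}, 18, "HQ"),
        (90, 2, {"5S": 1, "16S": 1, "23S": 1}, 20, "MQ"),  # needs strictly >90
        (60, 9.9, {}, 0, "MQ"),
        (60, 10.0, {}, 0, "LQ"),
    ])
    def test_gsc_tiers(self, comp, cont, rrna, trna, tier):
        assert classify_quality(QualityReport(comp, cont, rrna, trna)) == tier
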