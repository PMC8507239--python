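"""Strain grouping, chimera cleaning and greedy co-assembly."""

import pytest

from tests.conftest import make_assembly, mutate, random_seq
from sagbin import compare, groups, simulate
from sagbin.compare import QualityReport
from sagbin.groups import (StrainGroup, build_strain_groups, chimera_clean,
                           coassemble, make_nrsags, select_sags)
from sagbin.seqio import AssemblyKind, GenomeAssembly, ReadRecord


def _qr(c, cont):
    return QualityReport(c, cont)


class TestSelectSags:
    @pytest.mark.parametrize("comp,cont,kept", [
        (20.0, 1.0, False),   # strictly greater required
        (21.0, 9.9, True),
        (25.0, 10.0, False),  # strictly less required
    ])
    def test_strict_thresholds(self, comp, cont, kept):
        a = make_assembly({"c": "ACGT" * 300}, AssemblyKind.SAG, aid="s")
        out = select_sags([(a, _qr(comp, cont))], 20, 10)
        assert (len(out) == 1) == kept


@pytest.fixture(scope="module")
def marked_genome():
    spec = simulate.CommunitySpec(n_species=1, genome_len=50_000, strain_pairs=[],
                                  marker_count=20, seed=55)
    com = simulate.generate_references(spec)
    return com.refs.get("ref_s00"), com.markers


class TestBuildStrainGroups:
    def test_identical_sags_one_group(self, marked_genome):
        g, markers = marked_genome
        a = GenomeAssembly("sagA", g.contigs, AssemblyKind.SAG)
        b = GenomeAssembly("sagB", g.contigs, AssemblyKind.SAG)
        gs = build_strain_groups([a, b], markers)
        assert [g.member_ids for g in gs] == [["sagA", "sagB"]]

    def test_low_ani_pair_stays_separate(self, marked_genome):
        g, markers = marked_genome
        # ~5.1% genome-wide divergence: ANI below the 95 threshold
        diverged = mutate(g.contigs[0].seq, 0.051, seed=8)
        a = GenomeAssembly("sagA", g.contigs, AssemblyKind.SAG)
        b = make_assembly({"c": diverged}, AssemblyKind.SAG, aid="sagB")
        gs = build_strain_groups([a, b], markers)
        assert [grp.member_ids for grp in gs] == [["sagA"], ["sagB"]]

    def test_single_linkage_transitivity(self, marked_genome):
        g, markers = marked_genome
        seq = g.contigs[0].seq
        # A and C share no sequence; B overlaps both -> one group by linkage
        a = make_assembly({"c": seq[:22_000]}, AssemblyKind.SAG, aid="sagA")
        b = make_assembly({"c": seq}, AssemblyKind.SAG, aid="sagB")
        c = make_assembly({"c": seq[28_000:]}, AssemblyKind.SAG, aid="sagC")
        gs = build_strain_groups([a, b, c], markers)
        assert [grp.member_ids for grp in gs] == [["sagA", "sagB", "sagC"]]

    def test_permutation_invariant(self, marked_genome):
        g, markers = marked_genome
        seq = g.contigs[0].seq
        sags = [make_assembly({"c": seq[:30_000]}, AssemblyKind.SAG, aid="s1"),
                make_assembly({"c": seq[15_000:]}, AssemblyKind.SAG, aid="s2"),
                make_assembly({"c": mutate(seq, 0.051, seed=2)}, AssemblyKind.SAG, aid="s3")]
        g1 = build_strain_groups(sags, markers)
        g2 = build_strain_groups(sags[::-1], markers)
        assert [x.member_ids for x in g1] == [x.member_ids for x in g2]


@pytest.fixture(scope="module")
def sag_trio(marked_genome):
    g, markers = marked_genome
    sims = []
    for i, sd in enumerate((101, 202, 303)):
        spec = simulate.SagSimSpec(completeness_target=0.65, chimera_rate=0.05, seed=sd)
        sims.append(simulate.simulate_sag(g, spec, sag_id=f"sag{i}"))
    grp = StrainGroup([s.assembly.id for s in sims])
    reads = {s.assembly.id: s.reads for s in sims}
    asms = {s.assembly.id: s.assembly for s in sims}
    return g, markers, sims, grp, reads, asms


class TestChimeraClean:
    def test_clean_read_unchanged(self, sag_trio):
        g, _, sims, grp, reads, asms = sag_trio
        clean_reads = {s.assembly.id for s in sims}
        cleaned = chimera_clean(grp, reads, asms)
        for s in sims:
            chim = set(s.chimera_truth["read"])
            for r in s.reads:
                if r.id in chim:
                    continue
                frags = [f for f in cleaned[s.assembly.id].fragments
                         if f.read_id == r.id]
                assert len(frags) == 1 and frags[0].seq == r.seq

    def test_junctions_cut_within_10bp(self, sag_trio):
        _, _, sims, grp, reads, asms = sag_trio
        cleaned = chimera_clean(grp, reads, asms)
        ok = tot = 0
        for s in sims:
            log = cleaned[s.assembly.id].split_log
            for rid, j in zip(s.chimera_truth["read"], s.chimera_truth["junction"]):
                tot += 1
                ok += any(abs(c - j) <= 10 for c in log.get(rid, []))
        assert tot > 30
        assert ok / tot >= 0.95

    def test_never_gains_bases_and_min_fragment(self, sag_trio):
        _, _, sims, grp, reads, asms = sag_trio
        cleaned = chimera_clean(grp, reads, asms)
        for s in sims:
            before = sum(len(r.seq) for r in s.reads)
            after = sum(len(f.seq) for f in cleaned[s.assembly.id].fragments)
            assert after <= before
            assert all(len(f.seq) >= 20 for f in cleaned[s.assembly.id].fragments)

    def test_short_foreign_tail_discarded(self, marked_genome):
        g, _ = marked_genome
        seq = g.contigs[0].seq
        asm_a = make_assembly({"c": seq[:20_000]}, AssemblyKind.SAG, aid="A")
        asm_b = make_assembly({"c": seq[:20_000]}, AssemblyKind.SAG, aid="B")
        chimera = seq[5000:5120] + random_seq(777, 15)  # 120 real + 15 foreign
        reads = {"A": [ReadRecord("chim", chimera)], "B": []}
        cleaned = chimera_clean(StrainGroup(["A", "B"]), reads,
                                {"A": asm_a, "B": asm_b})
        frags = cleaned["A"].fragments
        assert len(frags) == 1
        assert frags[0].seq == seq[5000:5120]

    def test_singleton_group_passthrough(self, marked_genome):
        g, _ = marked_genome
        asm = make_assembly({"c": g.contigs[0].seq}, AssemblyKind.SAG, aid="A")
        reads = {"A": [ReadRecord("r", random_seq(1, 150))]}
        cleaned = chimera_clean(StrainGroup(["A"]), reads, {"A": asm})
        assert [f.seq for f in cleaned["A"].fragments] == [reads["A"][0].seq]


class TestCoassemble:
    def test_tiled_reads_reconstruct_template(self):
        tpl = random_seq(61, 5000)
        reads = [ReadRecord(f"r{i}", tpl[o:o + 150])
                 for i, o in enumerate(range(0, 4851, 50))]
        grp = StrainGroup(["A"])
        cleaned = {"A": groups.CleanedReads(
            reads, [groups.ReadFragment(r.id, 0, 150, r.seq) for r in reads], {})}
        cosag = coassemble(grp, cleaned, "cosag")
        assert [c.seq for c in cosag.contigs] == [tpl]

    def test_two_templates_two_contigs(self):
        t1, t2 = random_seq(62, 4000), random_seq(63, 3000)
        frags = [groups.ReadFragment(f"r{i}", 0, 150, t[o:o + 150])
                 for i, (t, o) in enumerate(
                     [(t1, o) for o in range(0, 3851, 50)]
                     + [(t2, o) for o in range(0, 2851, 50)])]
        cleaned = {"A": groups.CleanedReads([], frags, {})}
        cosag = coassemble(StrainGroup(["A"]), cleaned, "cosag")
        assert sorted(c.seq for c in cosag.contigs) == sorted([t1, t2])

    def test_all_short_pieces_empty_cosag(self, caplog):
        frags = [groups.ReadFragment("r", 0, 150, random_seq(i, 150)) for i in range(3)]
        cleaned = {"A": groups.CleanedReads([], frags, {})}
        cosag = coassemble(StrainGroup(["A"]), cleaned, "cosag")
        assert cosag.contigs == []

    def test_complementary_dropout_improves_completeness(self, sag_trio):
        g, markers, sims, grp, reads, asms = sag_trio
        cleaned = chimera_clean(grp, reads, asms)
        cosag = coassemble(grp, cleaned, "cosag")
        member_comp = max(compare.estimate_quality(a, markers).completeness
                          for a in asms.values())
        cosag_comp = compare.estimate_quality(cosag, markers).completeness
        assert cosag_comp >= member_comp


class TestMakeNrsags:
    def test_completeness_and_dedup_rules(self, marked_genome):
        g, markers = marked_genome
        seq = g.contigs[0].seq
        full = make_assembly({"c": seq}, AssemblyKind.COSAG, aid="full")        # 100%
        most = make_assembly({"c": seq[:40_000]}, AssemblyKind.COSAG, aid="most")  # ~80%
        half_minus = make_assembly({"c": seq[:24_000]}, AssemblyKind.COSAG, aid="halfm")
        out = make_nrsags([full, most, half_minus], markers)
        # full and most are near-identical (ANI ~100): only the more complete kept;
        # halfm sits at <=50% completeness: excluded by the strict rule
        assert [a.id for a in out] == ["full"]
        assert all(a.kind == AssemblyKind.NRSAG for a in out)

    def test_below_dedup_threshold_kept(self, marked_genome):
        g, markers = marked_genome
        seq = g.contigs[0].seq
        a = make_assembly({"c": seq}, AssemblyKind.COSAG, aid="a")
        b = make_assembly({"c": mutate(seq, 0.02, seed=4)}, AssemblyKind.COSAG, aid="b")
        out = make_nrsags([a, b], markers)
        assert [x.id for x in out] == ["a", "b"]
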