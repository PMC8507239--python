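"""Closest-reference assignment, coverage and precision/recall/F1."""

import numpy as np
import pytest

from tests.conftest import make_assembly, mutate, random_seq
from sagbin import pairwise
from sagbin.binning import UNBINNED, BinAssignment
from sagbin.evaluate import (UNASSIGNED, ReferenceSet, binning_error_totals,
                             closest_reference, genomic_coverage,
                             precision_recall_f1)
from sagbin.pairwise import SeedIndex
from sagbin.seqio import AssemblyKind, Contig, GenomeAssembly


@pytest.fixture(scope="module")
def refs():
    base = random_seq(301, 50_000)
    strain_a = make_assembly({"A_chrom": base}, aid="refA")
    strain_b = make_assembly({"B_chrom": mutate(base, 0.017, seed=302)}, aid="refB")
    other = make_assembly({"C_chrom": random_seq(303, 50_000)}, aid="refC")
    return ReferenceSet([strain_a, strain_b, other])


class TestClosestReference:
    def test_reference_finds_itself(self, refs):
        for g in refs:
            assert closest_reference(g, refs) == g.id

    def test_below_995_unassigned(self, refs):
        draft = make_assembly({"d": mutate(refs.get("refA").contigs[0].seq, 0.01,
                                           seed=304)}, aid="draft")
        assert closest_reference(draft, refs) == UNASSIGNED

    def test_strain_discrimination(self, refs):
        # draft at ~99.8% to strain A, ~98.3% to strain B
        draft = make_assembly({"d": mutate(refs.get("refA").contigs[0].seq, 0.002,
                                           seed=305)}, aid="draft")
        assert closest_reference(draft, refs) == "refA"


def brute_force_coverage(draft, ref) -> int:
    """Per-base oracle: mark every draft base inside any qualifying block."""
    idx = SeedIndex(ref, k=15)
    total = 0
    for c in draft.contigs:
        covered = np.zeros(len(c.seq), dtype=bool)
        for b in pairwise.align(c, idx, min_identity=0.9, min_len=100):
            covered[b.q_start:b.q_end] = True
        total += int(covered.sum())
    return total


class TestGenomicCoverage:
    def test_identical_draft_full_coverage(self, refs):
        ref = refs.get("refC")
        draft = GenomeAssembly("d", [Contig("d1", ref.contigs[0].seq)],
                               AssemblyKind.MGSAG)
        assert genomic_coverage(draft, ref) == draft.total_length

    def test_duplicated_region_counts_per_draft_interval(self, refs):
        ref = refs.get("refC")
        seq = ref.contigs[0].seq
        draft = GenomeAssembly("d", [Contig("d1", seq[:10_000]),
                                     Contig("d2", seq[:10_000])], AssemblyKind.MGSAG)
        assert genomic_coverage(draft, ref) == 20_000

    def test_unalignable_tail_excluded(self, refs):
        ref = refs.get("refC")
        draft = make_assembly({"d": ref.contigs[0].seq[:10_000] + random_seq(9, 1000)},
                              AssemblyKind.MGSAG, aid="d")
        L = genomic_coverage(draft, ref)
        assert L == pytest.approx(10_000, abs=30)

    def test_monotone_under_added_contigs(self, refs):
        ref = refs.get("refC")
        seq = ref.contigs[0].seq
        partial = GenomeAssembly("d", [Contig("d1", seq[:8000])], AssemblyKind.MGSAG)
        fuller = GenomeAssembly("d", [Contig("d1", seq[:8000]),
                                      Contig("d2", seq[20_000:30_000])],
                                AssemblyKind.MGSAG)
        assert genomic_coverage(fuller, ref) >= genomic_coverage(partial, ref)

    def test_matches_per_base_oracle_random_instances(self):
        rng = np.random.default_rng(306)
        ref_seq = random_seq(307, 30_000)
        ref = make_assembly({"r": ref_seq}, aid="ref")
        for trial in range(20):
            n = int(rng.integers(1, 4))
            contigs = []
            for i in range(n):
                s = int(rng.integers(0, 25_000))
                L = int(rng.integers(1000, 5000))
                piece = mutate(ref_seq[s:s + L], float(rng.uniform(0, 0.05)),
                               seed=int(rng.integers(2**31)))
                contigs.append(Contig(f"c{i}", piece))
            draft = GenomeAssembly("d", contigs, AssemblyKind.MGSAG)
            assert genomic_coverage(draft, ref) == brute_force_coverage(draft, ref)


class TestPrecisionRecallF1:
    def test_formulas(self):
        assert precision_recall_f1(900, 1000, 1000) == (0.9, 0.9, 0.9)

    def test_f1_equals_p_when_p_equals_r(self):
        p, r, f1 = precision_recall_f1(500, 1000, 1000)
        assert p == r == f1

    def test_zero_coverage(self):
        assert precision_recall_f1(0, 1000, 1000) == (0.0, 0.0, 0.0)

    def test_coverage_bug_detected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(1001, 1000, 1000)

    def test_f1_maximized_at_balance(self):
        # fixed P+R: F1 peaks where P == R
        balanced = precision_recall_f1(600, 1000, 1000)[2]
        skewed = 2 * 0.9 * 0.3 / 1.2
        assert balanced > skewed


class TestBinningErrorTotals:
    def _setup(self):
        ma = GenomeAssembly("ma", [Contig("m1", "A" * 5000), Contig("m2", "C" * 3000),
                                   Contig("m3", "G" * 2000)], AssemblyKind.MA)
        truth = {"m1": "refX", "m2": "refY", "m3": "refX"}
        return ma, truth

    def test_perfect_assignment_zero_incorrect(self):
        ma, truth = self._setup()
        assignment = BinAssignment({"m1": "nrX", "m2": "nrY", "m3": "nrX"})
        out = binning_error_totals(assignment, ma, truth,
                                   {"nrX": "refX", "nrY": "refY"})
        assert out.incorrectly_binned_bp == 0 and out.unbinned_bp == 0

    def test_misplaced_contig_counts_length(self):
        ma, truth = self._setup()
        assignment = BinAssignment({"m1": "nrY", "m2": "nrY", "m3": "nrX"})
        out = binning_error_totals(assignment, ma, truth,
                                   {"nrX": "refX", "nrY": "refY"})
        assert out.incorrectly_binned_bp == 5000

    def test_unbinned_contig_counts_length(self):
        ma, truth = self._setup()
        assignment = BinAssignment({"m1": "nrX", "m2": UNBINNED, "m3": "nrX"})
        out = binning_error_totals(assignment, ma, truth,
                                   {"nrX": "refX", "nrY": "refY"})
        assert out.unbinned_bp == 3000

    def test_unlabeled_bin_counts_incorrect(self):
        ma, truth = self._setup()
        assignment = BinAssignment({"m1": "nrZ", "m2": "nrY", "m3": "nrX"})
        out = binning_error_totals(assignment, ma, truth,
                                   {"nrX": "refX", "nrY": "refY", "nrZ": UNASSIGNED})
        assert out.incorrectly_binned_bp == 5000

    def test_missing_truth_errors(self):
        ma, truth = self._setup()
        del truth["m3"]
        assignment = BinAssignment({"m1": "nrX", "m2": "nrY", "m3": "nrX"})
        with pytest.raises(KeyError):
            binning_error_totals(assignment, ma, truth, {"nrX": "refX", "nrY": "refY"})
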