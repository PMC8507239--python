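"""Seeded benchmark experiments on synthetic communities.

These are the package's standard self-evaluation scenarios: guided binning
on a mock-style community, strain/plasmid resolution, the unbinned-length
vs. reference-completeness sweep, merge gain, ANI calibration and chimera
cleaning accuracy. Each function is deterministic given its seed and returns
plain dictionaries of measured quantities; the test suite asserts on them
and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import binning, compare, evaluate, groups, merge, simulate
from .binning import UNBINNED
from .pairwise import SeedIndex
from .seqio import AssemblyKind, Contig, GenomeAssembly
from .simulate import CommunitySpec, SagSimSpec, _random_seq, _mutate


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _nrsag_from(genome: GenomeAssembly, target: float, seed: int,
                window: int = 5000) -> GenomeAssembly:
    sim = simulate.simulate_sag(
        genome, SagSimSpec(completeness_target=target, dropout_window=window,
                           seed=seed), sag_id=f"nr_{genome.id}")
    return GenomeAssembly(sim.assembly.id, sim.assembly.contigs,
                          AssemblyKind.NRSAG, dict(sim.assembly.meta))


def binning_benchmark(seed: int, n_species: int = 10, genome_len: int = 200_000,
                      completeness_range: tuple[float, float] = (0.62, 0.90),
                      frag_mean: int = 20_000) -> dict:
    """Guided binning on the default mock-style community.

    One nrSAG per genome at 60-90% completeness guides the binning of a
    20 kb-fragment metagenome; returns per-species precision/recall/F1 of
    the resulting bins plus community-wide error totals.
    """
    s = _child_seeds(seed, 3 + n_species + 1)
    com = simulate.generate_references(CommunitySpec(
        n_species=n_species, genome_len=genome_len, seed=s[0]))
    rng = np.random.default_rng(s[1])
    nrsags = [_nrsag_from(g, float(rng.uniform(*completeness_range)), s[3 + i])
              for i, g in enumerate(com.refs)]
    ma, truth = simulate.simulate_metagenome(com, frag_mean=frag_mean, seed=s[2])
    assignment = binning.assign_contigs(ma, nrsags)
    sgbins = binning.build_sgbins(ma, assignment)
    indexes = {g.id: SeedIndex(g, k=15) for g in com.refs}
    bin_labels = {a.id: evaluate.closest_reference(a, com.refs, indexes=indexes)
                  for a in nrsags}
    community = evaluate.binning_error_totals(assignment, ma, truth, bin_labels)
    per_species = {}
    for b in sgbins:
        ref_id = bin_labels[b.meta["nrsag"]]
        ref = com.refs.get(ref_id)
        L = evaluate.genomic_coverage(b, ref, index=indexes[ref_id])
        p, r, f1 = evaluate.precision_recall_f1(L, b.total_length, ref.total_length)
        per_species[ref_id] = {"precision": p, "recall": r, "f1": f1}
    binned_bp = sum(len(c) for c in ma.contigs
                    if assignment.assignments[c.id] != UNBINNED)
    return {"per_species": per_species, "n_bins": len(sgbins),
            "n_genomes": len(com.refs.genomes),
            "incorrectly_binned_bp": community.incorrectly_binned_bp,
            "unbinned_bp": community.unbinned_bp, "binned_bp": binned_bp,
            "ma_bp": ma.total_length}


def strain_resolution_benchmark(seed: int, genome_len: int = 200_000,
                                divergence: float = 0.015,
                                plasmid_lens: tuple[int, int] = (30_000, 28_000),
                                nrsag_completeness: float = 0.9) -> dict:
    """Two strains at ~98.5% ANI, each with a unique ~30 kb plasmid.

    Bins the strain-pure metagenome against one nrSAG per strain and counts
    plasmid host assignments and cross-strain chromosome contigs.
    """
    s = _child_seeds(seed, 5)
    com = simulate.generate_references(CommunitySpec(
        n_species=1, genome_len=genome_len,
        strain_pairs=[(0, divergence, plasmid_lens)], seed=s[0]))
    strains = [com.refs.get("ref_s00a"), com.refs.get("ref_s00b")]
    ani = compare.ani(strains[0], strains[1]).ani
    nrsags = [_nrsag_from(g, nrsag_completeness, s[2 + i])
              for i, g in enumerate(strains)]
    ma, truth = simulate.simulate_metagenome(com, frag_mean=20_000, seed=s[1],
                                             consensus_rate=0.0)
    assignment = binning.assign_contigs(ma, nrsags)
    sgbins = binning.build_sgbins(ma, assignment)
    plasmid_total = plasmid_correct = cross_strain = 0
    for c in ma.contigs:
        bin_id = assignment.assignments[c.id]
        if bin_id == UNBINNED:
            continue
        binned_to = bin_id[len("nr_"):]
        src_contig = c.origin.split(":")[0]
        is_plasmid = com.refs.is_plasmid(truth[c.id], src_contig)
        if is_plasmid:
            plasmid_total += 1
            plasmid_correct += binned_to == truth[c.id]
        elif binned_to != truth[c.id]:
            cross_strain += 1
    return {"pair_ani": ani, "n_bins": len(sgbins),
            "plasmid_total": plasmid_total, "plasmid_correct": plasmid_correct,
            "cross_strain_chromosome_contigs": cross_strain}


def completeness_sweep(seed: int, genome_len: int = 100_000,
                       targets: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0)) -> dict:
    """Unbinned length against one target bin as its nrSAG completeness rises.

    The dropout series is nested (higher completeness retains a superset),
    so the sweep isolates the completeness effect.
    """
    s = _child_seeds(seed, 3)
    com = simulate.generate_references(CommunitySpec(
        n_species=2, genome_len=genome_len, strain_pairs=[], seed=s[0]))
    target_genome = com.refs.get("ref_s00")
    ma, truth = simulate.simulate_metagenome(com, frag_mean=10_000, seed=s[1])
    other = _nrsag_from(com.refs.get("ref_s01"), 0.8, s[2])
    out = {}
    for t in targets:
        sim = simulate.simulate_sag(
            target_genome, SagSimSpec(completeness_target=t, dropout_window=10_000,
                                      seed=s[2] ^ 0x5EED),
            sag_id=f"nr_{target_genome.id}")
        nrsag = GenomeAssembly(sim.assembly.id, sim.assembly.contigs,
                               AssemblyKind.NRSAG)
        assignment = binning.assign_contigs(ma, [nrsag, other])
        unbinned = sum(len(c) for c in ma.contigs
                       if truth[c.id] == target_genome.id
                       and assignment.assignments[c.id] == UNBINNED)
        out[t] = unbinned
    return out


def merge_gain_benchmark(seed: int, genome_len: int = 150_000) -> dict:
    """Complementary-dropout merge: an rRNA-bearing nrSAG plus an rRNA-less
    but more complete sgBin must merge into an HQ-classifiable draft."""
    s = _child_seeds(seed, 2)
    com = simulate.generate_references(CommunitySpec(
        n_species=1, genome_len=genome_len, strain_pairs=[], seed=s[0]))
    genome = com.refs.get("ref_s00")
    seq = genome.contigs[0].seq
    imp = com.implants
    rrna_iv = sorted((int(r.start), int(r.end)) for r in imp.itertuples()
                     if r.element in ("5S", "16S", "23S"))
    # sgBin: the genome minus every rRNA locus (plus margins) -> rRNA-less
    cut = [(max(0, a - 200), min(len(seq), b + 200)) for a, b in rrna_iv]
    sg_contigs, pos = [], 0
    for a, b in cut:
        if a - pos >= 1000:
            sg_contigs.append(seq[pos:a])
        pos = b
    sg_contigs.append(seq[pos:])
    sgbin = GenomeAssembly("sgBin_nr_ref_s00", [
        Contig(f"ma_{i:03d}", x) for i, x in enumerate(sg_contigs)],
        AssemblyKind.SGBIN, {"nrsag": "nr_ref_s00"})
    # nrSAG: less complete overall, but contiguous across the rRNA loci
    rng = np.random.default_rng(s[1])
    keep = np.ones(len(seq), dtype=bool)
    while keep.mean() > 0.8:
        start = int(rng.integers(0, len(seq) - 12_000))
        w = (start, start + 12_000)
        if all(w[1] <= a or w[0] >= b for a, b in cut):
            keep[w[0]:w[1]] = False
    nr_contigs = [seq[a:b] for a, b in simulate._runs(keep) if b - a >= 10_000]
    nrsag = GenomeAssembly("nr_ref_s00", [
        Contig(f"nr_{i:03d}", x) for i, x in enumerate(nr_contigs)],
        AssemblyKind.NRSAG)
    markers, rrna_refs = com.markers, com.rrna_refs
    comp_nr = compare.estimate_quality(nrsag, markers).completeness
    comp_sg = compare.estimate_quality(sgbin, markers).completeness
    primary, secondary, label = merge.choose_primary(nrsag, sgbin, markers)
    secondary = merge.filter_secondary(secondary)
    merged = merge.merge_assemblies(primary, secondary, label=label)
    q = compare.estimate_quality(merged, markers)
    rrna_sg, _ = merge.count_rna_genes(sgbin, rrna_refs)
    rrna_nr, _ = merge.count_rna_genes(nrsag, rrna_refs)
    annot = pd.DataFrame({"contig": [merged.contigs[0].id] * 20,
                          "start": range(20), "end": range(100, 120),
                          "strand": ["+"] * 20, "type": ["tRNA"] * 20})
    rrna_m, trna = merge.count_rna_genes(merged, rrna_refs, annot)
    rep_sg = compare.QualityReport(comp_sg, 0.0, rrna_sg, 20)
    rep_m = compare.QualityReport(q.completeness, q.contamination, rrna_m, trna)
    return {"label": label,
            "completeness_nrsag": comp_nr, "completeness_sgbin": comp_sg,
            "completeness_merged": q.completeness,
            "contamination_merged": q.contamination,
            "rrna_sgbin": rrna_sg, "rrna_nrsag": rrna_nr, "rrna_merged": rrna_m,
            "tier_sgbin": merge.classify_quality(rep_sg),
            "tier_merged": merge.classify_quality(rep_m)}


def ani_calibration(seed: int, genome_len: int = 100_000,
                    rates: tuple[float, ...] = (0.01, 0.03, 0.05)) -> dict:
    """Self-ANI plus estimates at fixed substitution rates."""
    s = _child_seeds(seed, 1 + len(rates))
    base = _random_seq(np.random.default_rng(s[0]), genome_len)
    target = GenomeAssembly("t", [Contig("c", base)], AssemblyKind.REFERENCE)
    out = {"self": compare.ani(target, target).ani}
    for i, m in enumerate(rates):
        mut, _ = _mutate(np.random.default_rng(s[1 + i]), base, m)
        q = GenomeAssembly("q", [Contig("c", mut)], AssemblyKind.SAG)
        out[m] = compare.ani(q, target).ani
    return out


def ani_separation_trials(seed: int, n_trials: int = 100,
                          genome_len: int = 30_000,
                          threshold: float = 95.0) -> dict:
    """Does the >95 ANI rule separate distant from close strain pairs?

    Per trial, two strains diverge independently from a common ancestor at
    4% (distant) or 0.5% (close) substitutions each, giving pairwise
    identities of ~92% and ~99%. Counts trials where the close pair exceeds
    the threshold and the distant pair does not.
    """
    seeds = _child_seeds(seed, n_trials)
    separated = 0
    for ts in seeds:
        rng = np.random.default_rng(ts)
        anc = _random_seq(rng, genome_len)
        ani_of = {}
        for d in (0.04, 0.005):
            a, _ = _mutate(rng, anc, d)
            b, _ = _mutate(rng, anc, d)
            ga = GenomeAssembly("a", [Contig("c", a)], AssemblyKind.SAG)
            gb = GenomeAssembly("b", [Contig("c", b)], AssemblyKind.SAG)
            res = compare.ani(ga, gb)
            ani_of[d] = res.ani if res.defined else 0.0
        if ani_of[0.005] > threshold >= ani_of[0.04]:
            separated += 1
    return {"n_trials": n_trials, "separated": separated}


def chimera_benchmark(seed: int, chimera_rate: float = 0.05,
                      genome_len: int = 50_000, n_sags: int = 3) -> dict:
    """Chimera-splitting accuracy on a same-strain SAG group."""
    s = _child_seeds(seed, 1 + n_sags)
    com = simulate.generate_references(CommunitySpec(
        n_species=1, genome_len=genome_len, strain_pairs=[],
        marker_count=20, seed=s[0]))
    genome = com.refs.get("ref_s00")
    sims = [simulate.simulate_sag(
        genome, SagSimSpec(completeness_target=0.65, chimera_rate=chimera_rate,
                           seed=s[1 + i]), sag_id=f"sag{i}")
        for i in range(n_sags)]
    grp = groups.StrainGroup([x.assembly.id for x in sims])
    cleaned = groups.chimera_clean(
        grp, {x.assembly.id: x.reads for x in sims},
        {x.assembly.id: x.assembly for x in sims})
    junctions = cut_ok = split_clean = 0
    min_frag = 10**9
    for x in sims:
        cl = cleaned[x.assembly.id]
        chim = dict(zip(x.chimera_truth["read"], x.chimera_truth["junction"]))
        for rid, j in chim.items():
            junctions += 1
            cut_ok += any(abs(c - j) <= 10 for c in cl.split_log.get(rid, []))
        split_clean += sum(1 for rid in cl.split_log if rid not in chim)
        if cl.fragments:
            min_frag = min(min_frag, min(len(f.seq) for f in cl.fragments))
    return {"junctions": junctions, "cut_within_10bp": cut_ok,
            "clean_reads_split": split_clean,
            "min_fragment_len": min_frag if min_frag < 10**9 else 0}
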