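"""End-to-end orchestration of the guided-binning workflow.

Each step consumes and produces plain data structures plus TSV/FASTA files,
so the steps can run standalone on prior outputs (the CLI wires them to
subcommands). The flow mirrors the workflow the package implements:

    simulate -> group (select, group, clean, co-assemble, nrSAGs)
             -> bin   (assign MA contigs, sgBins, unbinned)
             -> merge (primary/secondary, guided merge, quality tiers)
             -> evaluate (closest reference, precision/recall/F1, totals)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, binning, compare, evaluate, groups, merge, simulate
from .binning import BinAssignment
from .compare import MarkerSet, QualityReport
from .config import PipelineConfig
from .evaluate import CommunityEval, EvalResult, ReferenceSet
from .seqio import (AssemblyKind, GenomeAssembly, ReadRecord, assembly_stats,
                    write_fasta, write_fastq)

log = logging.getLogger(__name__)


@dataclass
class SimulatedDataset:
    community: simulate.SyntheticCommunity
    sags: list[GenomeAssembly]
    reads_by_sag: dict[str, list[ReadRecord]]
    chimera_truth: dict[str, pd.DataFrame]
    ma: GenomeAssembly
    ma_truth: dict[str, str]


@dataclass
class GroupOutputs:
    selected: list[GenomeAssembly]
    strain_groups: list[groups.StrainGroup]
    candidates: list[GenomeAssembly]
    nrsags: list[GenomeAssembly]
    table: pd.DataFrame


@dataclass
class MergeOutputs:
    drafts: list[tuple[GenomeAssembly, str]]  # (assembly, sgMAG/mgSAG label)
    quality: pd.DataFrame
    reports: dict[str, QualityReport] = field(default_factory=dict)


def run_simulate(cfg: PipelineConfig, seed: int) -> SimulatedDataset:
    """Generate the full synthetic dataset the downstream steps consume."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(4)
    pairs = [(0, cfg.sim_strain_divergence, tuple(cfg.sim_plasmid_lens))]
    spec = simulate.CommunitySpec(n_species=cfg.sim_n_species,
                                  genome_len=cfg.sim_genome_len,
                                  marker_count=cfg.sim_marker_count,
                                  strain_pairs=pairs,
                                  marker_snp_rate=cfg.sim_marker_snp_rate,
                                  seed=int(child[0].generate_state(1)[0] % 2**31))
    community = simulate.generate_references(spec)
    rng = np.random.default_rng(child[1])
    sags, reads_by_sag, chim = [], {}, {}
    lo, hi = cfg.sim_sag_completeness
    for g in community.refs:
        for rep in range(cfg.sim_sags_per_genome):
            target = float(rng.uniform(lo, hi))
            sspec = simulate.SagSimSpec(
                completeness_target=target, read_len=cfg.sim_read_len,
                depth=cfg.sim_depth, chimera_rate=cfg.sim_chimera_rate,
                dropout_window=cfg.sim_dropout_window,
                seed=int(rng.integers(2**31)))
            sim = simulate.simulate_sag(g, sspec, sag_id=f"sag_{g.id}_{rep}")
            sags.append(sim.assembly)
            reads_by_sag[sim.assembly.id] = sim.reads
            chim[sim.assembly.id] = sim.chimera_truth
    ma, ma_truth = simulate.simulate_metagenome(
        community, frag_mean=cfg.sim_frag_mean,
        seed=int(child[2].generate_state(1)[0] % 2**31))
    return SimulatedDataset(community, sags, reads_by_sag, chim, ma, ma_truth)


def run_group(sags: list[GenomeAssembly],
              reads_by_sag: dict[str, list[ReadRecord]],
              markers: MarkerSet, cfg: PipelineConfig) -> GroupOutputs:
    """Select usable SAGs, group same-strain SAGs, clean and co-assemble
    grouped reads, and collect non-redundant SAGs."""
    if not sags:
        raise ValueError("no SAG assemblies provided")
    scored = [(a, compare.estimate_quality(a, markers)) for a in sags]
    selected = groups.select_sags(scored, cfg.select_completeness_min,
                                  cfg.select_contamination_max)
    log.info("selected %d/%d SAGs", len(selected), len(sags))
    if not selected:
        raise ValueError("no SAG passed the quality selection")
    strain_groups = groups.build_strain_groups(
        selected, markers, ani_min=cfg.group_ani_min,
        homology_min=cfg.group_homology_min, tnf_min=cfg.group_tnf_min)
    log.info("formed %d strain group(s)", len(strain_groups))
    by_id = {a.id: a for a in selected}
    candidates = []
    for gi, grp in enumerate(strain_groups):
        if len(grp.member_ids) == 1:
            candidates.append(by_id[grp.member_ids[0]])
            continue
        cleaned = groups.chimera_clean(
            grp, reads_by_sag, by_id, max_cycles=cfg.chimera_max_cycles,
            min_anchor=cfg.chimera_min_anchor,
            min_fragment=cfg.chimera_min_fragment,
            full_cover=cfg.chimera_full_cover)
        extra = [c.seq for m in grp.member_ids if m not in cleaned
                 for c in by_id[m].contigs]
        if cleaned or extra:
            cosag = groups.coassemble(grp, cleaned, f"cosag_{gi:03d}",
                                      extra_pieces=extra,
                                      min_contig=cfg.contig_min_len)
            candidates.append(cosag)
    nrsags = groups.make_nrsags(candidates, markers,
                                completeness_min=cfg.nrsag_completeness_min,
                                contamination_max=cfg.nrsag_contamination_max,
                                dedup_ani=cfg.nrsag_dedup_ani)
    log.info("%d nrSAG(s) collected from %d candidate(s)", len(nrsags), len(candidates))
    rows = []
    for gi, grp in enumerate(strain_groups):
        for m in grp.member_ids:
            pair_ev = [v for k, v in grp.evidence.items() if m in k]
            ani_v = max((v[0] for v in pair_ev), default=float("nan"))
            hom_v = max((v[1] for v in pair_ev), default=float("nan"))
            tnf_v = max((v[2] for v in pair_ev), default=float("nan"))
            rows.append((f"group_{gi:03d}", m, round(ani_v, 4), round(hom_v, 4),
                         round(tnf_v, 6)))
    table = pd.DataFrame(rows, columns=["group", "member", "ani", "homology", "tnf_corr"])
    return GroupOutputs(selected, strain_groups, candidates, nrsags, table)


def run_bin(ma: GenomeAssembly, nrsags: list[GenomeAssembly],
            cfg: PipelineConfig) -> tuple[BinAssignment, list[GenomeAssembly], GenomeAssembly]:
    assignment = binning.assign_contigs(ma, nrsags,
                                        min_identity=cfg.bin_min_identity,
                                        min_len=cfg.bin_min_len)
    sgbins = binning.build_sgbins(ma, assignment)
    unbinned = binning.extract_unbinned(ma, assignment)
    log.info("binned %d contig(s) into %d sgBin(s); %d unbinned",
             sum(1 for v in assignment.assignments.values() if v != binning.UNBINNED),
             len(sgbins), len(unbinned.contigs))
    return assignment, sgbins, unbinned


def run_merge(nrsags: list[GenomeAssembly], sgbins: list[GenomeAssembly],
              markers: MarkerSet, rrna_refs, cfg: PipelineConfig,
              trna_annotation: pd.DataFrame | None = None) -> MergeOutputs:
    """Merge each nrSAG/sgBin pair and classify the quality of every draft."""
    sgbin_by_nrsag = {b.meta.get("nrsag", b.id): b for b in sgbins}
    drafts: list[tuple[GenomeAssembly, str]] = []
    for nrsag in sorted(nrsags, key=lambda a: a.id):
        sgbin = sgbin_by_nrsag.pop(nrsag.id, None)
        if sgbin is None or not sgbin.contigs:
            log.warning("nrSAG %s has no paired sgBin; passed through unmerged", nrsag.id)
            drafts.append((GenomeAssembly(nrsag.id, nrsag.contigs, AssemblyKind.MGSAG,
                                          dict(nrsag.meta)), "mgSAG"))
            continue
        primary, secondary, label = merge.choose_primary(nrsag, sgbin, markers)
        secondary = merge.filter_secondary(secondary, cfg.secondary_min_len)
        merged = merge.merge_assemblies(primary, secondary, label=label,
                                        min_identity=cfg.merge_min_identity,
                                        min_extension_overlap=cfg.merge_min_extension_overlap)
        merged = GenomeAssembly(f"{nrsag.id}_draft", merged.contigs, merged.kind,
                                dict(merged.meta))
        drafts.append((merged, label))
    for b in sgbin_by_nrsag.values():
        log.warning("sgBin %s has no paired nrSAG; passed through unmerged", b.id)
        drafts.append((b, "sgBin"))
    rows, reports = [], {}
    for draft, label in drafts:
        q = compare.estimate_quality(draft, markers)
        rrna, trna = merge.count_rna_genes(draft, rrna_refs, trna_annotation) \
            if rrna_refs is not None else ({"5S": 0, "16S": 0, "23S": 0}, 0)
        report = QualityReport(q.completeness, q.contamination, rrna, trna)
        report.tier = merge.classify_quality(report)
        reports[draft.id] = report
        st = assembly_stats(draft)
        rows.append((draft.id, label, round(q.completeness, 2), round(q.contamination, 2),
                     rrna["5S"], rrna["16S"], rrna["23S"], trna, report.tier,
                     st.n50, st.total_length))
    quality = pd.DataFrame(rows, columns=["draft", "label", "completeness",
                                          "contamination", "rrna_5S", "rrna_16S",
                                          "rrna_23S", "trna", "tier", "n50", "total_bp"])
    return MergeOutputs(drafts, quality, reports)


def run_evaluate(drafts: list[GenomeAssembly], refs: ReferenceSet,
                 cfg: PipelineConfig,
                 assignment: BinAssignment | None = None,
                 ma: GenomeAssembly | None = None,
                 ma_truth: dict[str, str] | None = None,
                 nrsags: list[GenomeAssembly] | None = None
                 ) -> tuple[list[EvalResult], CommunityEval | None]:
    """Per-draft precision/recall/F1 and, when a bin assignment plus truth
    labels are supplied, community-level error totals."""
    indexes = {g.id: compare.SeedIndex(g, k=15) for g in refs}
    results = [evaluate.evaluate_draft(d, refs, min_ani=cfg.closest_ref_ani_min,
                                       indexes=indexes)
               for d in sorted(drafts, key=lambda a: a.id)]
    community = None
    if assignment is not None and ma is not None and ma_truth is not None:
        anchors = nrsags if nrsags is not None else drafts
        bin_labels = {}
        for a in anchors:
            bin_labels[a.id] = evaluate.closest_reference(
                a, refs, min_ani=cfg.closest_ref_ani_min, indexes=indexes)
        community = evaluate.binning_error_totals(assignment, ma, ma_truth, bin_labels)
        community.per_bin = results
    return results, community


# ---------------------------------------------------------------------------
# filesystem layer


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path) -> Path:
    rows = [(str(p.relative_to(outdir)), _sha256(p))
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.tsv"]
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=["file", "sha256"]).to_csv(manifest, sep="\t", index=False)
    return manifest


def write_run_log(outdir: Path, step: str, cfg: PipelineConfig, seed: int | None) -> None:
    payload = {"tool": "sagbin", "version": __version__, "step": step,
               "seed": seed, "config": cfg.to_dict()}
    with open(outdir / f"run_log_{step}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def write_dataset(data: SimulatedDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    refs_dir = outdir / "refs"
    sags_dir = outdir / "sags"
    refs_dir.mkdir(exist_ok=True)
    sags_dir.mkdir(exist_ok=True)
    for g in data.community.refs:
        write_fasta(g, refs_dir / f"{g.id}.fasta")
    markers = data.community.markers
    with open(outdir / "markers.fasta", "w") as fh:
        for mid, seq in markers.markers.items():
            fh.write(f">{mid}\n{seq}\n")
    with open(outdir / "rrna_refs.fasta", "w") as fh:
        for cls, seqs in data.community.rrna_refs.items():
            for i, seq in enumerate(seqs):
                fh.write(f">{cls}_{i}\n{seq}\n")
    data.community.truth.to_csv(outdir / "truth_references.tsv", sep="\t", index=False)
    for sag in data.sags:
        if sag.contigs:
            write_fasta(sag, sags_dir / f"{sag.id}.fasta")
        write_fastq(data.reads_by_sag[sag.id], sags_dir / f"{sag.id}.fastq")
    write_fasta(data.ma, outdir / "ma.fasta")
    pd.DataFrame(sorted(data.ma_truth.items()), columns=["contig", "genome"]) \
        .to_csv(outdir / "truth_ma.tsv", sep="\t", index=False)


def write_group_outputs(out: GroupOutputs, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    nr_dir = outdir / "nrsags"
    nr_dir.mkdir(exist_ok=True)
    out.table.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    for a in out.nrsags:
        write_fasta(a, nr_dir / f"{a.id}.fasta")


def write_bin_outputs(assignment: BinAssignment, sgbins: list[GenomeAssembly],
                      unbinned: GenomeAssembly, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bins_dir = outdir / "sgbins"
    bins_dir.mkdir(exist_ok=True)
    assignment.table().to_csv(outdir / "bin_assignments.tsv", sep="\t", index=False)
    for b in sgbins:
        write_fasta(b, bins_dir / f"{b.id}.fasta")
    if unbinned.contigs:
        write_fasta(unbinned, outdir / "unbinned.fasta")


def write_merge_outputs(out: MergeOutputs, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    drafts_dir = outdir / "drafts"
    drafts_dir.mkdir(exist_ok=True)
    out.quality.to_csv(outdir / "quality.tsv", sep="\t", index=False)
    for draft, label in out.drafts:
        if draft.contigs:
            write_fasta(draft, drafts_dir / f"{draft.id}.fasta")


def write_eval_outputs(results: list[EvalResult], community: CommunityEval | None,
                       outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(r.draft_id, r.ref_id, r.L, round(r.precision, 6), round(r.recall, 6),
          round(r.f1, 6)) for r in results],
        columns=["draft", "reference", "L_bp", "precision", "recall", "f1"]) \
        .to_csv(outdir / "eval_drafts.tsv", sep="\t", index=False)
    if community is not None:
        pd.DataFrame([(community.incorrectly_binned_bp, community.unbinned_bp)],
                     columns=["incorrectly_binned_bp", "unbinned_bp"]) \
            .to_csv(outdir / "eval_community.tsv", sep="\t", index=False)


def run_all(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    """simulate -> group -> bin -> merge -> evaluate, writing every report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = run_simulate(cfg, seed)
    write_dataset(data, outdir / "simulate")
    grp = run_group(data.sags, data.reads_by_sag, data.community.markers, cfg)
    write_group_outputs(grp, outdir / "group")
    assignment, sgbins, unbinned = run_bin(data.ma, grp.nrsags, cfg)
    write_bin_outputs(assignment, sgbins, unbinned, outdir / "bin")
    merged = run_merge(grp.nrsags, sgbins, data.community.markers,
                       data.community.rrna_refs, cfg)
    write_merge_outputs(merged, outdir / "merge")
    results, community = run_evaluate(
        [d for d, _ in merged.drafts], data.community.refs, cfg,
        assignment=assignment, ma=data.ma, ma_truth=data.ma_truth,
        nrsags=grp.nrsags)
    write_eval_outputs(results, community, outdir / "evaluate")
    write_run_log(outdir, "run_all", cfg, seed)
    write_manifest(outdir)
    return {"n_sags": len(data.sags), "n_nrsags": len(grp.nrsags),
            "n_sgbins": len(sgbins), "n_drafts": len(merged.drafts),
            "incorrectly_binned_bp": community.incorrectly_binned_bp if community else None,
            "unbinned_bp": community.unbinned_bp if community else None}
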