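"""Pipeline configuration: one schema holding every threshold.

The defaults are the recommended operating point of the workflow
(grouping 95/99/0.90, nrSAG filter 50/10, binning 0.99/200, 10 kb secondary
floor, 99.5 closest-taxon ANI); a YAML file overrides any subset. The SAG
selection completeness floor has two published profiles: 10 (mock
communities) and 20 (host-associated samples).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # SAG selection (strict inequalities)
    select_completeness_min: float = 10.0
    select_contamination_max: float = 10.0
    # strain grouping criteria (strict inequalities)
    group_ani_min: float = 95.0
    group_homology_min: float = 99.0
    group_tnf_min: float = 0.90
    # chimera cleaning
    chimera_max_cycles: int = 3
    chimera_min_anchor: int = 30
    chimera_min_fragment: int = 20
    chimera_full_cover: float = 0.9
    # co-assembly
    coassembly_min_overlap: int = 40
    contig_min_len: int = 1000
    # nrSAG collection
    nrsag_completeness_min: float = 50.0
    nrsag_contamination_max: float = 10.0
    nrsag_dedup_ani: float = 99.5
    # guided binning (strict inequalities)
    bin_min_identity: float = 0.99
    bin_min_len: int = 200
    # guided merging
    secondary_min_len: int = 10000
    merge_min_identity: float = 0.99
    merge_min_extension_overlap: int = 1000
    # evaluation
    closest_ref_ani_min: float = 99.5
    coverage_min_identity: float = 0.9
    # synthetic community
    sim_n_species: int = 10
    sim_genome_len: int = 200_000
    sim_marker_count: int = 40
    sim_strain_divergence: float = 0.015
    sim_plasmid_lens: tuple[int, int] = (30_000, 25_000)
    # realistic strains carry SNPs inside marker genes too; without them the
    # marker-homology criterion cannot tell the pair's strains apart
    sim_marker_snp_rate: float = 0.015
    sim_frag_mean: int = 20_000
    sim_sag_completeness: tuple[float, float] = (0.55, 0.85)
    sim_sags_per_genome: int = 2
    sim_read_len: int = 150
    sim_depth: int = 3
    sim_chimera_rate: float = 0.05
    sim_dropout_window: int = 5000
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and keyword
    overrides; unknown keys are all reported at once."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(PipelineConfig.__dataclass_fields__)
    bad = sorted(set(data) - valid)
    if bad:
        raise ValueError(f"unknown config key(s): {', '.join(bad)}")
    for key in ("sim_sag_completeness", "sim_plasmid_lens"):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)
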