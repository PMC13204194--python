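"""Pipeline configuration: every stage threshold in one serialisable object.

Defaults are the operating values of the analysis this package implements:
TPM floor 10 with 2-of-3 low samples, DRG cutoffs p < 0.01 and |logFC| >
0.5, GSEA with 1000 permutations and weight 1, expression calling with a
4-cycle medium separation and a 27.5 high-abundance Ct cutoff, 2-of-3
database consensus, pathway alpha 0.05, and a minimum survival group of 8.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # low-expression filter
    tpm_threshold: float = 10.0
    min_low_samples: int = 2
    filter_scope: str = "either_group"
    # differential expression / DRG calling
    pseudocount: float = 1.0
    p_cut: float = 0.01
    lfc_cut: float = 0.5
    # enrichment
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    top_k: int = 10
    enrich_alpha: float = 0.05
    # miRNA cards
    min_delta: float = 4.0
    ntc_ct_floor: float = 35.0
    ct_cut: float = 27.5
    # target integration / convergence
    min_db: int = 2
    alpha: float = 0.05
    # survival
    min_group: int = 8
    scan_mode: str = "scan"
    # master seed for every stochastic stage
    seed: int = 0
    # synthetic-data problem sizes (simulate mode)
    sim_n_transcripts: int = 20000
    sim_n_per_group: int = 3
    sim_de_fraction: float = 0.05
    sim_effect_log2fc: float = 2.0
    sim_dispersion: float = 0.3
    sim_low_fraction: float = 0.7
    sim_n_mirnas: int = 136
    sim_n_preps: int = 3
    sim_expressed_fraction: float = 0.2
    sim_high_fraction: float = 0.5
    sim_spike_ct: float = 23.852
    sim_medium_offset_ct: float = 6.0
    sim_noise_sd: float = 0.3
    sim_per_db_density: float = 0.02
    sim_consensus_overlap: float = 0.3
    sim_n_dbs: int = 3
    sim_n_genesets: int = 50
    sim_set_size: list[int] = field(default_factory=lambda: [10, 80])
    sim_n_planted_sets: int = 5
    sim_n_patients: int = 127
    sim_hazard_ratio: float = 3.0
    sim_censor_rate: float = 0.3

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **overrides) -> "PipelineConfig":
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)
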