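"""Pipeline configuration with defaults matching the published thresholds."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class ExpressionConfig:
    cpm_threshold: float = 1.0       # CPM > 1 ...
    min_reps: int = 2                # ... in >= 2 of 3 replicates per stage
    cpm_basis: str = "raw"           # or "tmm": CPM filter basis
    lfc_threshold: float = 2.0       # |log2FC| > 2
    alpha: float = 0.05              # BH-adjusted p < 0.05
    n_clusters: int = 6
    pseudo_count: float = 1.0        # log2(x + 1) before relative expression


@dataclass
class SplicingConfig:
    min_junction_reads: int = 10
    min_total_cov: int = 25          # strictly greater than
    rare_min_expr: int = 5           # minor isoform support >= 5
    rare_min_ratio: float = 0.05     # minor isoform ratio > 5%
    min_clean_overhang: int = 6      # bases free of mismatch/indel at the overhang
    delta_psi: float = 0.1           # |dPSI| > 0.1
    pvalue: float = 0.05
    fdr: float = 0.05


@dataclass
class EditingConfig:
    min_base_q: int = 25
    min_map_q: int = 25
    min_alt_reads: int = 3
    min_alt_freq: float = 0.03
    min_depth: int = 10
    dna_min_depth: int = 10          # rule (iii) coverage floor; value chosen, see docs
    dna_max_alt_frac: float = 0.0    # strictest reading: no non-reference DNA reads
    splice_exclusion_nt: int = 4     # exclude sites within 4 nt of a splice boundary
    min_replicates: int = 2          # present in >= 2 replicates of a stage
    mode: str = "per_replicate"      # or "merged"


@dataclass
class EnrichmentConfig:
    pvalue_cutoff: float = 0.2
    qvalue_cutoff: float = 0.2


@dataclass
class Config:
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    splicing: SplicingConfig = field(default_factory=SplicingConfig)
    editing: EditingConfig = field(default_factory=EditingConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None) -> Config:
    """Defaults, overridden by any keys present in the YAML file."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for section, values in data.items():
        target = getattr(cfg, section, None)
        if target is None or not isinstance(values, dict):
            continue
        for key, val in values.items():
            if hasattr(target, key):
                setattr(target, key, val)
    return cfg
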