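"""Pipeline configuration: one document, CLI flags override."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Defaults follow the study's stated analysis parameters: 100-kb CNV
    bins, 0.5 compartment change-ratio threshold, 90% TAD overlap, 5-bin
    loop window, 100/10 SNP-density cutoffs per 100 kb, 1.5-fold
    prediction tolerance."""

    # synthetic genome
    chromosomes: list = field(default_factory=lambda: [["chr1", 4_000_000], ["chr21", 2_000_000]])
    snp_rate: float = 1e-3
    trisomy_chrom: str = "chr21"
    trisomy_origin: str = "maternal"
    # library sizes
    wgs_coverage: float = 5.0
    frag_len: int = 150
    rna_fragments: int = 100_000
    n_contacts: int = 200_000
    cis_fraction: float = 0.9993
    n_genes: int = 150
    expression_noise_sd: float = 0.2
    # analysis parameters (paper-stated defaults)
    cnv_bin_size: int = 100_000
    compartment_bin_size: int = 50_000
    compartment_change_threshold: float = 0.5
    tad_overlap_threshold: float = 0.9
    loop_window: int = 5
    snp_density_window: int = 100_000
    high_snp_excess: int = 100
    low_snp_max: int = 10
    accuracy_tolerance_fold: float = 1.5
    seed: int = 0

    def validate(self):
        positive = [
            self.cnv_bin_size, self.compartment_bin_size, self.tad_overlap_threshold,
            self.loop_window, self.snp_density_window, self.high_snp_excess,
            self.low_snp_max, self.accuracy_tolerance_fold, self.compartment_change_threshold,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
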