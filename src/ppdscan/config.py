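"""Run configuration: every stage threshold in one validated structure.

Defaults are the published analysis values: 10 kb windows with 2 kb slides,
weighted F_ST > 0.6 with >= 10 variants per window, XP-EHH region threshold
2.0, per-site INDEL F_ST selection threshold 0.2, EHH truncation cutoff
0.05, reference-is-ancestral derived-allele policy, recessive concordance
model, and a top-10 association listing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # inputs (leave empty to simulate them first)
    vcf: str = ""
    ped: str = ""
    gtf: str = ""
    fasta: str = ""
    outdir: str = "ppdscan_out"
    simulate: bool = True  # generate a synthetic dataset into outdir first

    # windows shared by F_ST and XP-EHH region calling
    window_span_bp: int = 10_000
    window_step_bp: int = 2_000

    # F_ST thresholds
    fst_min_weighted: float = 0.6
    fst_min_variants: int = 10
    indel_site_fst_threshold: float = 0.2  # per-site INDEL selection

    # XP-EHH
    xpehh_threshold: float = 2.0
    ehh_cutoff: float = 0.05
    xpehh_normalize: bool = True
    xpehh_max_extend_bp: float = 100_000.0  # bounded flank integration

    # association / concordance
    ancestral_policy: str = "reference"  # or "AA"
    concordance_model: str = "recessive"
    top_k_assoc: int = 10

    # prioritization
    gene_flank_bp: int = 0

    # filtering
    cluster_window_bp: int = 10
    cluster_min_snps: int = 3

    seed: int = 0
    sim: dict = field(default_factory=dict)  # overrides for SimConfig fields

    def validate(self) -> None:
        if self.window_span_bp < self.window_step_bp:
            raise ConfigError("window_span_bp must be >= window_step_bp")
        if self.ancestral_policy not in ("reference", "AA"):
            raise ConfigError(f"unknown ancestral_policy {self.ancestral_policy!r}")
        if self.concordance_model not in ("recessive", "dominant"):
            raise ConfigError(f"unknown concordance_model {self.concordance_model!r}")
        if not (0 < self.ehh_cutoff < 1):
            raise ConfigError("ehh_cutoff must lie in (0, 1)")
        if self.top_k_assoc < 1:
            raise ConfigError("top_k_assoc must be >= 1")
        if not self.simulate and not (self.vcf and self.ped and self.gtf and self.fasta):
            raise ConfigError("vcf/ped/gtf/fasta paths are required when simulate is false")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
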