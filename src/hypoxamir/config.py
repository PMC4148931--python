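"""Pipeline configuration: one flat, YAML-serializable parameter set.

Every stage parameter carries the analysis default (1.5-fold DE threshold,
16-35 nt length window, <=2 elimination mismatches, 70 nt candidate flanks,
5 kb HRE span, >=3-source target consensus); loading and dumping round-trip
exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from hypoxamir.errors import ConfigurationError
from hypoxamir.synthetic import DEFAULT_ADAPTER


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "out"
    # synthetic input (simulate=True) or explicit FASTQ + reference paths
    simulate: bool = True
    fastq_normoxic: str | None = None
    fastq_hypoxic: str | None = None
    reference_dir: str | None = None
    # preprocess
    adapter: str = DEFAULT_ADAPTER
    adapter_min_overlap: int = 8
    adapter_max_mismatches: int = 1
    min_len: int = 16
    max_len: int = 35
    # annotate
    max_mismatches: int = 2
    flank: int = 70
    # quantify
    de_threshold: float = 1.5
    pseudocount: int = 1
    cluster_gap: int = 10000
    # isomiR grouping
    isomir_max_offset5: int = 3
    isomir_max_offset3: int = 4
    isomir_max_nta: int = 2
    # novel hairpin filter
    hairpin_min_score: int = 25
    hairpin_loop_min: int = 3
    hairpin_loop_max: int = 20
    hairpin_min_paired_frac: float = 0.6
    # promoter HRE scan
    hre_span: int = 5000
    hre_motif: str = "RCGTG"
    # target consensus
    min_support: int = 3
    n_target_sources: int = 5

    def validate(self) -> None:
        if self.min_len <= 0 or self.min_len > self.max_len:
            raise ConfigurationError("need 0 < min_len <= max_len")
        if self.de_threshold <= 1.0:
            raise ConfigurationError("DE threshold must exceed 1")
        if self.hre_span <= 0 or self.flank < 0:
            raise ConfigurationError("spans must be positive")
        if self.min_support < 1 or self.min_support > self.n_target_sources:
            raise ConfigurationError(
                "min_support must lie in [1, n_target_sources]"
            )
        if not self.simulate:
            for field_ in ("fastq_normoxic", "fastq_hypoxic", "reference_dir"):
                if getattr(self, field_) is None:
                    raise ConfigurationError(
                        f"{field_} is required when simulate is false"
                    )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
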