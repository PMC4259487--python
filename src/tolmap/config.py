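"""Pipeline configuration: one structured key-value file plus overrides.

Parameter defaults carry the study's printed constants: 1000 bp
enrichment intervals, a 9-read candidate threshold supported by at least
2 samples, ~250 bp sheared fragments read as 75 bp paired ends, and an
FPKM >= 1 expression gate in the reference sample.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class Paths:
    reference: str = ""
    construct: str = ""
    reads_r1: list[str] = field(default_factory=list)  # one per sample
    reads_r2: list[str] = field(default_factory=list)
    sams: list[str] = field(default_factory=list)  # alternative to reads
    sample_ids: list[str] = field(default_factory=list)
    genotype_table: str = ""
    parent_genotypes: str = ""
    counts: str = ""


@dataclass
class Parameters:
    bin_size: int = 1000
    min_reads: int = 9
    min_samples: int = 2
    alpha: float = 0.05
    n_boot: int = 999
    bootstrap_mode: str = "max_count"
    seed: int = 0
    read_len: int = 75
    fragment_mean: int = 250
    fragment_sd: int = 30
    enrichment: float = 50.0
    error_rate: float = 0.0
    copy_number: int = 10
    tsd_len: int = 8
    genome_length: int = 1_000_000
    construct_length: int = 5000
    n_pairs: int = 20000
    n_samples: int = 5
    min_exact_seed: int = 20
    repeat_k: int = 25
    repeat_max_copy: float = 2.0
    q_threshold: float = 0.05
    fc_threshold: float = 2.0
    fpkm_threshold: float = 1.0
    pseudocount: float = 1.0
    qvalue_method: str = "storey"
    # synthetic linkage / counts defaults
    n_transgenic: int = 100
    n_nontransgenic: int = 100
    n_genes: int = 2000
    de_fraction: float = 0.05
    fold_change: float = 8.0
    dispersion: float = 0.0
    library_size: int = 2_000_000


@dataclass
class PipelineConfig:
    paths: Paths = field(default_factory=Paths)
    parameters: Parameters = field(default_factory=Parameters)

    def validate(self) -> None:
        p = self.parameters
        checks = [
            (p.bin_size > 0, "bin_size must be > 0"),
            (p.min_reads >= 1, "min_reads must be >= 1"),
            (p.min_samples >= 1, "min_samples must be >= 1"),
            (0 < p.alpha <= 1, "alpha must be in (0, 1]"),
            (p.n_boot >= 1, "n_boot must be >= 1"),
            (p.bootstrap_mode in ("per_interval", "max_count"), "bootstrap_mode invalid"),
            (p.read_len > 0, "read_len must be > 0"),
            (p.read_len <= p.fragment_mean, "read_len must not exceed fragment_mean"),
            (p.enrichment >= 1, "enrichment must be >= 1"),
            (0 <= p.error_rate < 1, "error_rate must be in [0, 1)"),
            (p.copy_number >= 1, "copy_number must be >= 1"),
            (p.tsd_len >= 0, "tsd_len must be >= 0"),
            (0 <= p.de_fraction <= 1, "de_fraction must be in [0, 1]"),
            (p.fold_change > 0, "fold_change must be > 0"),
            (p.dispersion >= 0, "dispersion must be >= 0"),
            (p.fpkm_threshold >= 0, "fpkm_threshold must be >= 0"),
            (p.q_threshold > 0, "q_threshold must be > 0"),
            (p.fc_threshold >= 1, "fc_threshold must be >= 1"),
            (p.qvalue_method in ("storey", "bh"), "qvalue_method invalid"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, target in (("paths", cfg.paths), ("parameters", cfg.parameters)):
            for key, value in (raw.get(section) or {}).items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown config field {section}.{key}")
                setattr(target, key, value)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {"paths": asdict(self.paths), "parameters": asdict(self.parameters)}
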