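"""Pipeline-wide thresholds and constants.

All classification thresholds used across the pipeline live in one frozen
dataclass so every stage reports the exact values it ran with.  Defaults are
the published operating point of the analysis this package implements:
covered fraction > 0.40, |log2 coverage ratio| > 2, Student's t p < 0.01 for
subgenome assignment; 201 bp SNP segments matched at >= 196 identical bases
with >= 5 continuous segments for anchoring; a synonymous substitution rate
of 1.3e-8 per site per year for LTR dating; 1 Mb SNP-density windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    # subgenome assignment
    covered_fraction_min: float = 0.40
    log2_ratio_min: float = 2.0
    ttest_alpha: float = 0.01
    equal_var: bool = True          # classic Student's t; False -> Welch
    normalize_depths: bool = True   # divide by dataset genome-wide mean depth
    pseudocount: float = 0.01       # normalized-depth units, added in the log ratio
    mapq_min: int = 20              # upstream read filter; documentation only

    # pseudochromosome anchoring
    segment_length: int = 201
    segment_min_match: int = 196
    min_continuous_segments: int = 5
    max_run_gap: int = 0            # tolerated missing markers inside a run
    gap_size: int = 100             # N spacer between scaffolds in built chromosomes

    # hybrid scaffold detection
    hybrid_window: int = 10_000
    hybrid_min_segment: int = 50_000
    terminal_fraction: float = 0.10  # sub-telomeric band, per chromosome end

    # LTR dating and family clustering
    substitution_rate_r: float = 1.3e-8  # per site per year
    age_bin_years: float = 5.0e5
    evalue_max: float = 1.0e-5

    # lineage-specific SNPs and density scan
    min_allele_depth: int = 3
    density_window: int = 1_000_000
    density_z: float = 2.0

    # homoeolog expression
    bias_log2_threshold: float = 1.0
    expression_pseudocount: float = 1.0
    expression_floor: float = 5.0
    specificity_factor: float = 2.0
    kmeans_k: int = 8

    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "covered_fraction_min", "log2_ratio_min", "ttest_alpha",
            "segment_length", "segment_min_match", "min_continuous_segments",
            "hybrid_window", "hybrid_min_segment", "substitution_rate_r",
            "density_window", "density_z", "bias_log2_threshold",
            "age_bin_years", "evalue_max", "specificity_factor",
            "terminal_fraction", "kmeans_k",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.segment_min_match > self.segment_length:
            raise ValueError("segment_min_match cannot exceed segment_length")
        if not 0 < self.covered_fraction_min < 1:
            raise ValueError("covered_fraction_min must be a proportion in (0, 1)")
        if not 0 < self.ttest_alpha < 1:
            raise ValueError("ttest_alpha must be a probability in (0, 1)")

    @property
    def max_mismatches(self) -> int:
        """Substitutions tolerated in a segment match (201 - 196 = 5 by default)."""
        return self.segment_length - self.segment_min_match

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a YAML (or key: value) file; unset keys keep defaults."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
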