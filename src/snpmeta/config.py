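"""Pipeline configuration.

Every numeric rule the pipeline applies (frequency-concordance thresholds,
palindromic ambiguity window, HWE alpha, influence cutoffs, bias gates) is a
field here so that analyses are reproducible from a single config file.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # eligibility
    min_studies: int = 4

    # harmonization / QC
    switch_maf_delta: float = 0.2    # reported freq must deviate from reference MAF by more than this
    switch_match_tol: float = 0.1    # ... and agree with 1 - MAF within this, to call a label switch
    palindromic_low: float = 0.4     # A/T and C/G SNPs with reference MAF inside
    palindromic_high: float = 0.6    # [low, high] cannot be oriented and are excluded
    hwe_alpha: float = 0.05
    hwe_method: str = "exact"        # "exact" or "chisq"
    # ancestry label -> reference-panel population
    population_map: dict[str, str] = field(
        default_factory=lambda: {"Asian": "EAS", "Caucasian": "EUR"}
    )

    # effect extraction
    trio_se_literal: bool = False    # report 1/C_T + 1/C_N without the square root
    ci_se_literal: bool = False      # report CI_up - OR on the odds-ratio scale

    # diagnostics
    outlier_z: float = 1.96
    dffits_mult: float = 3.0         # influential if |DFFITS| > mult * sqrt(1/(k-1))
    covratio_mult: float = 3.0       # ... or COVRATIO < 1 - mult/(k-1)

    # publication bias
    bias_min_k: int = 10
    bias_alpha: float = 0.05
    trimfill_estimator: str = "L0"   # "L0" or "R0"
    trimfill_max_iter: int = 50

    # combination with GWAS
    i2_random_switch: float = 75.0   # per-cent; above this the combined Z uses random effects
    exclude_caucasian_candidates: bool = True
    candidate_entry: str = "pooled"  # "pooled" (one RE effect per SNP) or "study"

    # reporting
    alpha: float = 0.05
    bonferroni_n: int | None = None  # None -> number of meta-analysed SNPs

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_studies < 1:
            raise ValueError("min_studies must be positive")
        if not 0 <= self.palindromic_low <= self.palindromic_high <= 1:
            raise ValueError("palindromic window must satisfy 0 <= low <= high <= 1")
        if self.trimfill_estimator not in ("L0", "R0"):
            raise ValueError("trimfill_estimator must be 'L0' or 'R0'")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError("hwe_method must be 'exact' or 'chisq'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a TOML file; unknown keys raise."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
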