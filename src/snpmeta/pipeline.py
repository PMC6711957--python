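"""Per-SNP orchestration and the dataset-level report.

For each SNP the pipeline harmonizes every study to the reference panel,
applies the minimum-study eligibility rule per population stratum, pools
under fixed and DerSimonian–Laird random effects, runs outlier/influence and
HWE sensitivity re-analyses, and — for SNPs with enough studies — assesses
publication bias.  Dataset-level reporting adds summary statistics, the
Bonferroni threshold over the number of meta-analysed SNPs, and optionally
the expanded combination with GWAS summary data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bias import BiasAssessment, assess_bias
from .config import PipelineConfig
from .diagnostics import SensitivityResult, sensitivity_reanalysis
from .gwas import CombinedResult, expanded_meta
from .harmonize import HarmonizedStudy, HweResult, align_to_reference, hwe_test
from .meta import MetaResult
from .records import GwasSummaryRecord, ReferenceTable, StudyRecord


@dataclass(frozen=True)
class StratumReport:
    population: str
    eligible: bool
    k_usable: int
    sensitivity: Optional[SensitivityResult] = None  # None iff ineligible
    bias: Optional[BiasAssessment] = None

    @property
    def primary(self) -> Optional[MetaResult]:
        return self.sensitivity.primary if self.sensitivity else None

    @property
    def presented(self) -> Optional[MetaResult]:
        return self.sensitivity.presented if self.sensitivity else None


@dataclass(frozen=True)
class SnpReport:
    snp_id: str
    harmonization: list[HarmonizedStudy]
    hwe: list[HweResult]
    strata: dict[str, StratumReport]

    @property
    def analyzed(self) -> bool:
        return any(s.eligible for s in self.strata.values())

    def results(self) -> dict[str, MetaResult | None]:
        """Primary MetaResult per stratum (None when ineligible)."""
        return {pop: s.primary for pop, s in self.strata.items()}

    def presented_results(self) -> dict[str, MetaResult | None]:
        return {pop: s.presented for pop, s in self.strata.items()}


def bonferroni_threshold(n_snps: int, *, alpha: float = 0.05) -> float:
    """Familywise significance level: alpha / number of meta-analysed SNPs."""
    if n_snps < 1:
        raise ValueError("need at least one test")
    return alpha / n_snps


def run_snp(
    records: Sequence[StudyRecord],
    reference: ReferenceTable,
    config: PipelineConfig | None = None,
) -> SnpReport:
    """Full analysis of one SNP: harmonize, filter, pool, diagnose, assess bias."""
    cfg = config or PipelineConfig()
    if not records:
        raise ValueError("no records supplied")
    snp_id = records[0].snp_id
    if any(r.snp_id != snp_id for r in records):
        raise ValueError("run_snp expects records for a single SNP")

    harmonized, hwe_results = [], []
    for rec in records:
        population = cfg.population_map.get(rec.ancestry, "")
        harmonized.append(align_to_reference(rec, reference, population, cfg))
        hw = hwe_test(rec, cfg)
        if hw is not None:
            hwe_results.append(hw)

    usable = [(h, r) for h, r in zip(harmonized, records) if not h.excluded]
    groups = {
        "All": [h.estimate for h, _ in usable],
        "Asian": [h.estimate for h, r in usable if r.ancestry == "Asian"],
        "Caucasian": [h.estimate for h, r in usable if r.ancestry == "Caucasian"],
    }
    strata: dict[str, StratumReport] = {}
    for population, ests in groups.items():
        if len(ests) < cfg.min_studies:
            strata[population] = StratumReport(population=population, eligible=False,
                                               k_usable=len(ests))
            continue
        sens = sensitivity_reanalysis(ests, hwe_results, population=population,
                                      config=cfg)
        bias = assess_bias(ests, population=population, config=cfg)
        strata[population] = StratumReport(population=population, eligible=True,
                                           k_usable=len(ests), sensitivity=sens,
                                           bias=bias)
    return SnpReport(snp_id=snp_id, harmonization=harmonized, hwe=hwe_results,
                     strata=strata)


@dataclass
class DatasetSummary:
    n_snps_input: int
    n_snps_analyzed: int
    median_studies: Optional[float]
    iqr_studies: tuple[float, float] | None
    median_sample_size: Optional[float]
    iqr_sample_size: tuple[float, float] | None


@dataclass
class AnalysisResult:
    reports: dict[str, SnpReport]
    summary: DatasetSummary
    bonferroni_alpha: float
    nominal_snps: list[str] = field(default_factory=list)
    bonferroni_snps: list[str] = field(default_factory=list)
    combined: dict[str, CombinedResult] = field(default_factory=dict)


def _quartiles(values: list[float]) -> tuple[Optional[float], tuple[float, float] | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return float(q2), (float(q1), float(q3))


def run_all(
    records: Sequence[StudyRecord],
    reference: ReferenceTable,
    gwas_records: Sequence[GwasSummaryRecord] = (),
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Analyse every SNP in the dataset and assemble the dataset-level report.

    The Bonferroni denominator is the number of SNPs with at least one
    eligible stratum (configurable).  A SNP counts as nominally significant
    when any stratum's presented random-effects p — i.e. after sensitivity
    exclusions where they occurred — beats ``alpha``.
    """
    cfg = config or PipelineConfig()
    by_snp: dict[str, list[StudyRecord]] = {}
    for rec in records:
        by_snp.setdefault(rec.snp_id, []).append(rec)

    reports = {snp: run_snp(recs, reference, cfg) for snp, recs in by_snp.items()}
    analyzed = {snp: rep for snp, rep in reports.items() if rep.analyzed}

    k_values, n_values = [], []
    for rep in analyzed.values():
        all_stratum = rep.strata["All"]
        res = all_stratum.primary
        if res is not None:
            k_values.append(res.k)
            if res.n_cases is not None and res.n_controls is not None:
                n_values.append(res.n_cases + res.n_controls)
    med_k, iqr_k = _quartiles(k_values)
    med_n, iqr_n = _quartiles([float(v) for v in n_values])

    n_tests = cfg.bonferroni_n or max(1, len(analyzed))
    bonf = bonferroni_threshold(n_tests, alpha=cfg.alpha)

    nominal, bonferroni_hits = [], []
    for snp, rep in analyzed.items():
        ps = [s.presented.p_random for s in rep.strata.values()
              if s.eligible and s.presented is not None]
        if not ps:
            continue
        best = min(ps)
        if best < cfg.alpha:
            nominal.append(snp)
        if best < bonf:
            bonferroni_hits.append(snp)

    combined: dict[str, CombinedResult] = {}
    if gwas_records:
        presented = {snp: rep.presented_results() for snp, rep in analyzed.items()}
        combined = expanded_meta(presented, gwas_records, config=cfg)

    summary = DatasetSummary(
        n_snps_input=len(by_snp), n_snps_analyzed=len(analyzed),
        median_studies=med_k, iqr_studies=iqr_k,
        median_sample_size=med_n, iqr_sample_size=iqr_n,
    )
    return AnalysisResult(reports=reports, summary=summary, bonferroni_alpha=bonf,
                          nominal_snps=sorted(nominal),
                          bonferroni_snps=sorted(bonferroni_hits),
                          combined=combined)


def result_rows(result: AnalysisResult) -> list[dict]:
    """Flatten an AnalysisResult into SNP x population x model rows for I/O."""
    rows = []
    for snp in sorted(result.reports):
        rep = result.reports[snp]
        for population in ("All", "Asian", "Caucasian"):
            stratum = rep.strata.get(population)
            if stratum is None or not stratum.eligible:
                continue
            res = stratum.presented
            for model in ("random", "fixed"):
                if model == "random":
                    ae, se, p = res.pooled_ae_random, res.se_random, res.p_random
                    ci = res.ci_random
                else:
                    ae, se, p = res.pooled_ae_fixed, res.se_fixed, res.p_fixed
                    ci = res.ci_fixed
                rows.append(dict(
                    snp_id=snp, population=population, model=model, k=res.k,
                    n_cases=res.n_cases, n_controls=res.n_controls,
                    pooled_ae=ae, se=se, or_value=float(np.exp(ae)),
                    ci_low=ci[0], ci_up=ci[1], p_value=p,
                    q_stat=res.q_stat, i2=res.i2, tau2=res.tau2,
                ))
    return rows
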