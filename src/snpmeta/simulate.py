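"""Synthetic study collections with the structure the pipeline assumes.

The generator draws, per SNP, a collection of case-control and trio studies
whose true allelic log OR varies between studies as Normal(theta, tau^2),
then passes them through a "reporting" layer that can inject the artefacts
the pipeline is built to correct: publication bias (significance-dependent
publishing), strand errors (allele labels complemented), allele-label
switches (labels swapped without touching the counts), HWE violations in
contaminated studies (inbreeding coefficient F), and loss of counts for
studies that only report summary statistics.

Defaults emulate the published candidate-gene literature the analysis
targets: a median of five studies per SNP, a few hundred cases and controls
per study, and reference minor-allele frequencies between 0.05 and 0.5.
The generator emits the exact TSV formats the I/O layer reads, so it doubles
as the fixture generator for every test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .effects import extract_effect
from .meta import two_sided_p
from .records import (COMPLEMENT, GenotypeCounts, GwasSummaryRecord,
                      ReferenceFrequency, ReferenceTable, Statistics,
                      StudyRecord, TrioCounts)

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class GwasCohortSpec:
    cohort_id: str
    n_cases: int
    n_controls: int
    ancestry: str = "Asian"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_snps: int = 20
    studies_per_snp: Optional[int] = None   # None -> 3 + Geometric(0.4), median 5
    n_cases: Optional[int] = None           # None -> lognormal, median ~550
    n_controls: Optional[int] = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    theta: float = math.log(1.2)            # true allelic log OR
    tau2: float = 0.05                      # between-study variance
    # publication rule: always publish if p < publish_alpha, else w.p. publish_gamma
    publish_alpha: float = 0.05
    publish_gamma: float = 1.0              # 1.0 -> no publication bias
    strand_error_rate: float = 0.0
    label_switch_rate: float = 0.0
    hwe_contamination_rate: float = 0.0
    hwe_f: float = 0.3                      # inbreeding coefficient of contaminated studies
    trio_fraction: float = 0.1
    stats_only_fraction: float = 0.2
    palindromic_fraction: float = 0.15
    asian_fraction: float = 0.5             # remaining studies are Caucasian
    gwas_cohorts: tuple[GwasCohortSpec, ...] = ()
    populations: tuple[str, ...] = ("EAS", "EUR")

    def __post_init__(self) -> None:
        for name in ("publish_alpha", "publish_gamma", "strand_error_rate",
                     "label_switch_rate", "hwe_contamination_rate",
                     "trio_fraction", "stats_only_fraction",
                     "palindromic_fraction", "asian_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


@dataclass(frozen=True)
class SnpTruth:
    """Ground truth for one simulated SNP, kept for recovery checks."""

    snp_id: str
    theta: float
    tau2: float
    maf: float
    minor_allele: str
    major_allele: str


def _hwe_genotype_probs(p: float, f: float) -> tuple[float, float, float]:
    """Genotype frequencies for allele-1 frequency p under inbreeding F."""
    q = 1 - p
    return (p * p + f * p * q, max(0.0, 2 * p * q * (1 - f)), q * q + f * p * q)


def simulate_case_control_study(
    theta_i: float, maf: float, n_case: int, n_ctrl: int,
    rng: np.random.Generator,
    *, snp_id: str = "rs1", study_id: str = "s1", ancestry: str = "Asian",
    allele_1: str = "A", allele_2: str = "G", hwe_f: float = 0.0,
) -> StudyRecord:
    """One case-control study under the allelic odds model.

    Controls carry allele_1 at frequency ``maf``; cases at
    logistic(logit(maf) + theta_i).  Genotypes are drawn multinomially from
    HWE proportions (or with inbreeding ``hwe_f`` for contaminated studies),
    which makes the implied allele counts Binomial(2n, freq) when F = 0.
    """
    p_case = 1.0 / (1.0 + math.exp(-(math.log(maf / (1 - maf)) + theta_i)))
    case_g = rng.multinomial(n_case, _hwe_genotype_probs(p_case, hwe_f))
    ctrl_g = rng.multinomial(n_ctrl, _hwe_genotype_probs(maf, hwe_f))
    return StudyRecord(
        study_id=study_id, snp_id=snp_id, ancestry=ancestry, design="case_control",
        allele_1=allele_1, allele_2=allele_2,
        genotype_counts=GenotypeCounts(*map(int, case_g), *map(int, ctrl_g)),
    )


def simulate_trio_study(
    theta_i: float, n_trios: int, rng: np.random.Generator,
    *, snp_id: str = "rs1", study_id: str = "s1", ancestry: str = "Asian",
    allele_1: str = "A", allele_2: str = "G",
) -> StudyRecord:
    """One trio study: transmissions ~ Binomial(n, exp(theta)/(1+exp(theta)))."""
    pt = math.exp(theta_i) / (1 + math.exp(theta_i))
    t = int(rng.binomial(n_trios, pt))
    return StudyRecord(
        study_id=study_id, snp_id=snp_id, ancestry=ancestry, design="family",
        allele_1=allele_1, allele_2=allele_2,
        trio_counts=TrioCounts(t, n_trios - t),
    )


def _strip_to_statistics(record: StudyRecord) -> StudyRecord:
    """Replace counts with the (OR, p) the study would have reported."""
    est = extract_effect(record)
    p = min(1.0 - 1e-12, max(1e-300, two_sided_p(est.ae / est.se_ae)))
    freq = record.control_freq_allele1()
    if math.exp(est.ae) == 1.0:  # degenerate for the p-route; keep counts
        return record
    return StudyRecord(
        study_id=record.study_id, snp_id=record.snp_id, ancestry=record.ancestry,
        design=record.design, allele_1=record.allele_1, allele_2=record.allele_2,
        statistics=Statistics(or_value=math.exp(est.ae), p_value=p),
        reported_freq_allele1=freq,
    )


def _with_alleles(record: StudyRecord, a1: str, a2: str) -> StudyRecord:
    return StudyRecord(
        study_id=record.study_id, snp_id=record.snp_id, ancestry=record.ancestry,
        design=record.design, allele_1=a1, allele_2=a2,
        pubmed_id=record.pubmed_id, genotype_counts=record.genotype_counts,
        allele_counts=record.allele_counts, statistics=record.statistics,
        trio_counts=record.trio_counts,
        reported_freq_allele1=record.reported_freq_allele1,
    )


def apply_reporting_filters(
    records: Sequence[StudyRecord], config: SimulationConfig,
    rng: np.random.Generator,
) -> list[StudyRecord]:
    """Publication rule and reporting errors, applied study by study.

    A study is published with certainty when its own Wald p beats
    ``publish_alpha`` and with probability ``publish_gamma`` otherwise.
    Published studies then independently suffer a strand error (both allele
    labels complemented — harmless once harmonized), a label switch (labels
    swapped while the counts stay put — a sign error unless caught by the
    frequency check), or are reduced to summary statistics.
    """
    out = []
    for rec in records:
        est = extract_effect(rec)
        p = two_sided_p(est.ae / est.se_ae)
        if p >= config.publish_alpha and rng.random() > config.publish_gamma:
            continue
        if rng.random() < config.stats_only_fraction and rec.design == "case_control":
            rec = _strip_to_statistics(rec)
        if rng.random() < config.strand_error_rate:
            rec = _with_alleles(rec, COMPLEMENT[rec.allele_1], COMPLEMENT[rec.allele_2])
        if rng.random() < config.label_switch_rate:
            rec = _with_alleles(rec, rec.allele_2, rec.allele_1)
        out.append(rec)
    return out


def _draw_k(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.studies_per_snp is not None:
        return config.studies_per_snp
    return 3 + int(rng.geometric(0.4))  # support >= 4, median 5, right-skewed


def _draw_n(config: SimulationConfig, which: str, rng: np.random.Generator) -> int:
    fixed = config.n_cases if which == "cases" else config.n_controls
    if fixed is not None:
        return fixed
    return max(50, int(rng.lognormal(math.log(550), 0.5)))


def simulate_snp(
    snp_index: int, config: SimulationConfig, seed_seq: np.random.SeedSequence,
) -> tuple[SnpTruth, list[StudyRecord]]:
    """All published studies for one SNP, reproducible from the master seed.

    Each SNP gets its own child RNG stream, so per-SNP results do not depend
    on how many other SNPs the dataset contains.
    """
    rng = np.random.default_rng(seed_seq)
    snp_id = f"rs{1000 + snp_index}"
    lo, hi = config.maf_range
    maf = float(rng.uniform(lo, hi))
    if rng.random() < config.palindromic_fraction:
        a1, a2 = _PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))]
    else:
        a1, a2 = _NONPALINDROMIC_PAIRS[int(rng.integers(len(_NONPALINDROMIC_PAIRS)))]
    truth = SnpTruth(snp_id=snp_id, theta=config.theta, tau2=config.tau2,
                     maf=maf, minor_allele=a1, major_allele=a2)
    k = _draw_k(config, rng)
    studies = []
    for j in range(k):
        theta_i = float(rng.normal(config.theta, math.sqrt(config.tau2)))
        ancestry = "Asian" if rng.random() < config.asian_fraction else "Caucasian"
        sid = f"{snp_id}_study{j}"
        if rng.random() < config.trio_fraction:
            n_trios = _draw_n(config, "cases", rng)
            studies.append(simulate_trio_study(
                theta_i, n_trios, rng, snp_id=snp_id, study_id=sid,
                ancestry=ancestry, allele_1=a1, allele_2=a2))
        else:
            f = config.hwe_f if rng.random() < config.hwe_contamination_rate else 0.0
            studies.append(simulate_case_control_study(
                theta_i, maf, _draw_n(config, "cases", rng),
                _draw_n(config, "controls", rng), rng,
                snp_id=snp_id, study_id=sid, ancestry=ancestry,
                allele_1=a1, allele_2=a2, hwe_f=f))
    return truth, apply_reporting_filters(studies, config, rng)


def build_reference(truths: Sequence[SnpTruth],
                    populations: Sequence[str] = ("EAS", "EUR")) -> ReferenceTable:
    """Reference MAF table matching the simulated truth in every population."""
    table = ReferenceTable()
    for t in truths:
        for pop in populations:
            table.add(ReferenceFrequency(
                snp_id=t.snp_id, population=pop, minor_allele=t.minor_allele,
                maf=t.maf, major_allele=t.major_allele))
    return table


def simulate_dataset(
    config: SimulationConfig, seed: int,
) -> tuple[list[SnpTruth], list[StudyRecord], ReferenceTable]:
    """A full synthetic dataset: truths, published study records, reference."""
    master = np.random.SeedSequence(seed)
    children = master.spawn(config.n_snps)
    truths, records = [], []
    for i, child in enumerate(children):
        truth, studies = simulate_snp(i, config, child)
        truths.append(truth)
        records.extend(studies)
    return truths, records, build_reference(truths, config.populations)


def simulate_gwas_summary(
    theta: float, cohorts: Sequence[GwasCohortSpec], rng: np.random.Generator,
    *, snp_id: str = "rs1", maf: float = 0.3,
    effect_allele: str = "A", other_allele: str = "G",
) -> list[GwasSummaryRecord]:
    """Per-cohort GWAS summary effects: beta ~ Normal(theta, se^2).

    The cohort SE is the large-sample SE of an allelic log OR at the given
    MAF and the cohort's case/control counts.
    """
    out = []
    for c in cohorts:
        pq = maf * (1 - maf)
        se = math.sqrt(1.0 / (2 * c.n_cases * pq) + 1.0 / (2 * c.n_controls * pq))
        beta = float(rng.normal(theta, se))
        out.append(GwasSummaryRecord(
            snp_id=snp_id, effect_allele=effect_allele, other_allele=other_allele,
            beta=beta, se=se, p=two_sided_p(beta / se),
            n=c.n_cases + c.n_controls, cohort_id=c.cohort_id, ancestry=c.ancestry))
    return out
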