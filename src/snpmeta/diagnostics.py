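"""Outlier and influence diagnostics for a pooled SNP, and sensitivity re-analysis.

All deleted quantities come from genuine leave-one-out refits: removing study
i, re-estimating tau^2 on the remaining k-1 studies, and re-pooling.  A study
is an outlier when its studentized deleted residual exceeds ``outlier_z`` in
absolute value, and influential when its DFFITS or COVRATIO crosses the
configured cutoffs.  The sensitivity re-analysis re-pools after dropping
(a) outliers and influential studies, and separately (b) HWE-violating
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import PipelineConfig
from .effects import EffectEstimate
from .harmonize import HweResult
from .meta import MetaResult, dersimonian_laird_meta


@dataclass(frozen=True)
class StudyDiagnostics:
    study_id: str
    deleted_ae: float       # random-effects pool with this study removed
    deleted_se: float
    deleted_tau2: float
    t_resid: float          # studentized deleted residual
    dffits: float
    dfbetas: float          # == dffits for the intercept-only model
    covratio: float
    outlier: bool
    influential: bool


@dataclass(frozen=True)
class DiagnosticsReport:
    snp_id: str
    population: str
    per_study: list[StudyDiagnostics]
    primary: MetaResult

    @property
    def outliers(self) -> list[str]:
        return [d.study_id for d in self.per_study if d.outlier]

    @property
    def influentials(self) -> list[str]:
        return [d.study_id for d in self.per_study if d.influential]


@dataclass(frozen=True)
class SensitivityResult:
    """Primary result plus the two exclusion-based re-analyses."""

    primary: MetaResult
    diagnostics: Optional[DiagnosticsReport]
    after_outlier_exclusion: Optional[MetaResult]   # None if nothing excluded or ineligible
    after_hwe_exclusion: Optional[MetaResult]
    excluded_outlier_ids: list[str] = field(default_factory=list)
    excluded_hwe_ids: list[str] = field(default_factory=list)
    outlier_ineligible: bool = False   # exclusions pushed k below the minimum
    hwe_ineligible: bool = False

    @property
    def presented(self) -> MetaResult:
        """The headline result: the outlier-sensitivity re-pool when
        exclusions occurred and remained eligible, else the primary."""
        if self.after_outlier_exclusion is not None:
            return self.after_outlier_exclusion
        return self.primary


def leave_one_out(
    estimates: Sequence[EffectEstimate], *, population: str = "All",
) -> list[MetaResult]:
    """k deleted random-effects pools, tau^2 re-estimated for each subset."""
    ests = list(estimates)
    if len(ests) < 3:
        raise ValueError("leave-one-out needs at least three studies")
    return [
        dersimonian_laird_meta(ests[:i] + ests[i + 1:], population=population)
        for i in range(len(ests))
    ]


def compute_diagnostics(
    estimates: Sequence[EffectEstimate],
    *, population: str = "All", config: PipelineConfig | None = None,
) -> DiagnosticsReport:
    """Per-study outlier and influence statistics from leave-one-out refits.

    t_i   = (ae_i - pooled_(-i)) / sqrt(se_i^2 + tau2_(-i) + se_(-i)^2)
    DFFITS_i   = (pooled - pooled_(-i)) / se_(-i)
    COVRATIO_i = var_(-i) / var_full
    """
    cfg = config or PipelineConfig()
    ests = list(estimates)
    full = dersimonian_laird_meta(ests, population=population)
    deleted = leave_one_out(ests, population=population)
    k = len(ests)
    dffits_cut = cfg.dffits_mult * math.sqrt(1.0 / (k - 1))
    covratio_cut = 1.0 - cfg.covratio_mult / (k - 1)
    rows = []
    for e, d in zip(ests, deleted):
        t = (e.ae - d.pooled_ae_random) / math.sqrt(
            e.se_ae**2 + d.tau2 + d.se_random**2)
        dffits = (full.pooled_ae_random - d.pooled_ae_random) / d.se_random
        covratio = d.se_random**2 / full.se_random**2
        rows.append(StudyDiagnostics(
            study_id=e.study_id,
            deleted_ae=d.pooled_ae_random, deleted_se=d.se_random,
            deleted_tau2=d.tau2, t_resid=t, dffits=dffits, dfbetas=dffits,
            covratio=covratio,
            outlier=abs(t) > cfg.outlier_z,
            influential=(abs(dffits) > dffits_cut) or (covratio < covratio_cut),
        ))
    return DiagnosticsReport(snp_id=full.snp_id, population=population,
                             per_study=rows, primary=full)


def studentized_deleted_residuals(
    estimates: Sequence[EffectEstimate], *, config: PipelineConfig | None = None,
) -> list[float]:
    return [d.t_resid for d in compute_diagnostics(estimates, config=config).per_study]


def influence_measures(
    estimates: Sequence[EffectEstimate], *, config: PipelineConfig | None = None,
) -> tuple[list[float], list[float], list[float]]:
    """(dffits, dfbetas, covratio) per study."""
    rep = compute_diagnostics(estimates, config=config)
    return ([d.dffits for d in rep.per_study],
            [d.dfbetas for d in rep.per_study],
            [d.covratio for d in rep.per_study])


def sensitivity_reanalysis(
    estimates: Sequence[EffectEstimate],
    hwe_results: Sequence[HweResult] | None = None,
    *, population: str = "All", config: PipelineConfig | None = None,
) -> SensitivityResult:
    """Primary pool plus re-pools excluding flagged and HWE-violating studies.

    Outliers and influential studies form one exclusion set; studies whose
    controls deviate from HWE form a second, independent one.  A re-analysis
    whose exclusions drop the stratum below the eligibility minimum is
    reported as ineligible rather than pooled.
    """
    cfg = config or PipelineConfig()
    ests = list(estimates)
    primary = dersimonian_laird_meta(ests, population=population)

    diag = None
    flagged: set[str] = set()
    if len(ests) >= 3:
        diag = compute_diagnostics(ests, population=population, config=cfg)
        flagged = set(diag.outliers) | set(diag.influentials)

    def _repool(excluded: set[str]) -> tuple[Optional[MetaResult], bool]:
        if not excluded:
            return None, False
        keep = [e for e in ests if e.study_id not in excluded]
        if len(keep) < cfg.min_studies:
            return None, True
        return dersimonian_laird_meta(keep, population=population), False

    after_out, out_inel = _repool(flagged)
    hwe_viol = {r.study_id for r in (hwe_results or []) if r.violates}
    hwe_viol &= {e.study_id for e in ests}
    after_hwe, hwe_inel = _repool(hwe_viol)

    return SensitivityResult(
        primary=primary, diagnostics=diag,
        after_outlier_exclusion=after_out, after_hwe_exclusion=after_hwe,
        excluded_outlier_ids=sorted(flagged), excluded_hwe_ids=sorted(hwe_viol),
        outlier_ineligible=out_inel, hwe_ineligible=hwe_inel,
    )
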