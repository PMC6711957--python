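"""Expanded meta-analysis: candidate-gene effects combined with GWAS summaries.

SNPs that reach nominal significance in the candidate-gene meta-analysis are
combined with per-cohort GWAS summary effects by inverse variance.  The
combined Z uses a fixed-effects model unless heterogeneity across inputs is
pronounced (I^2 above a configured switch point, 75% by default), in which
case the DerSimonian–Laird random-effects Z is reported.  By default the
candidate-gene side enters as its single pooled random-effects estimate, and
Caucasian candidate strata are excluded from combination (their samples are
assumed to overlap large Caucasian GWAS panels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import PipelineConfig
from .harmonize import _freq_discordant
from .meta import MetaResult, dl_tau2, fixed_effects_meta, heterogeneity, two_sided_p
from .records import COMPLEMENT, GwasSummaryRecord, ReferenceTable


@dataclass(frozen=True)
class AlignedGwas:
    record: Optional[GwasSummaryRecord]  # None iff excluded
    action: str
    note: str = ""

    @property
    def excluded(self) -> bool:
        return self.record is None


@dataclass(frozen=True)
class CombinedResult:
    snp_id: str
    inputs: tuple[str, ...]   # cohort ids and candidate stratum labels
    k: int
    beta: float
    se: float
    z_stat: float
    p: float
    model: str                # "fixed" | "random"
    i2_across_inputs: float
    q_stat: float


def _flip(rec: GwasSummaryRecord, *, negate: bool, complement: bool,
          swap: bool) -> GwasSummaryRecord:
    ea, oa = rec.effect_allele, rec.other_allele
    if complement:
        ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
    if swap:
        ea, oa = oa, ea
    return GwasSummaryRecord(
        snp_id=rec.snp_id, effect_allele=ea, other_allele=oa,
        beta=-rec.beta if negate else rec.beta, se=rec.se, p=rec.p, n=rec.n,
        cohort_id=rec.cohort_id, ancestry=rec.ancestry,
        from_or_scale=rec.from_or_scale)


def align_gwas_alleles(
    records: Sequence[GwasSummaryRecord],
    reference: ReferenceTable,
    population: str,
    *, effect_allele_freq: dict[str, float] | None = None,
    config: PipelineConfig | None = None,
) -> list[AlignedGwas]:
    """Orient GWAS effects to the reference minor allele on the forward strand.

    Mirrors the candidate-study decision procedure.  ``effect_allele_freq``
    optionally maps snp_id to the cohort's effect-allele frequency for the
    concordance check and palindromic orientation; palindromic SNPs with no
    frequency are excluded.
    """
    cfg = config or PipelineConfig()
    freqs = effect_allele_freq or {}
    out: list[AlignedGwas] = []
    for rec in records:
        ref = reference.lookup(rec.snp_id, population)
        if ref is None:
            out.append(AlignedGwas(rec, "unchanged",
                                   note=f"{rec.snp_id} absent from reference"))
            continue
        pair = frozenset((rec.effect_allele, rec.other_allele))
        comp = frozenset(COMPLEMENT[a] for a in pair)
        f_ea = freqs.get(rec.snp_id)
        if rec.is_palindromic:
            if pair != ref.alleles:
                out.append(AlignedGwas(None, "excluded_unresolved"))
                continue
            if cfg.palindromic_low <= ref.maf <= cfg.palindromic_high or f_ea is None:
                out.append(AlignedGwas(None, "excluded_ambiguous",
                                       note="palindromic; frequency-undecidable"))
                continue
            swap = rec.effect_allele != ref.minor_allele
            f_minor = f_ea if not swap else 1 - f_ea
            if (f_minor < 0.5) != (ref.maf < 0.5):
                aligned = _flip(rec, negate=not swap, complement=False, swap=swap)
                out.append(AlignedGwas(aligned, "allele_switched"))
            else:
                aligned = _flip(rec, negate=swap, complement=False, swap=swap)
                out.append(AlignedGwas(aligned, "unchanged"))
            continue
        if pair == ref.alleles:
            complement = False
        elif comp == ref.alleles:
            complement = True
        else:
            out.append(AlignedGwas(None, "excluded_unresolved"))
            continue
        ea = COMPLEMENT[rec.effect_allele] if complement else rec.effect_allele
        swap = ea != ref.minor_allele
        switched = False
        if f_ea is not None:
            f_minor = f_ea if not swap else 1 - f_ea
            if _freq_discordant(f_minor, ref.maf, cfg):
                switched = True
        negate = swap != switched  # orient beta to the reference minor allele
        aligned = _flip(rec, negate=negate, complement=complement, swap=swap)
        if complement and switched:
            action = "strand_flipped_and_switched"
        elif complement:
            action = "strand_flipped"
        elif switched:
            action = "allele_switched"
        else:
            action = "unchanged"
        out.append(AlignedGwas(aligned, action))
    return out


def gate_nominal(
    candidate_results: dict[str, dict[str, MetaResult | None]],
    *, alpha: float = 0.05,
) -> list[str]:
    """SNPs whose candidate random-effects p is nominally significant in any
    analyzed stratum; these proceed to the expanded combination stage."""
    passed = []
    for snp_id, strata in candidate_results.items():
        ps = [r.p_random for r in strata.values() if r is not None and not r.degenerate]
        if ps and min(ps) < alpha:
            passed.append(snp_id)
    return passed


def combine_inverse_variance(
    inputs: Sequence[tuple[str, float, float]],
    *, snp_id: str = "", config: PipelineConfig | None = None,
) -> CombinedResult:
    """Inverse-variance combination of (label, beta, se) inputs.

    Fixed-effects Z unless I^2 across inputs exceeds the configured switch
    point, in which case the DL random-effects Z is used.
    """
    cfg = config or PipelineConfig()
    if len(inputs) < 2:
        raise ValueError("combination needs at least two inputs")
    labels = tuple(lab for lab, _, _ in inputs)
    betas = [b for _, b, _ in inputs]
    ses = [s for _, _, s in inputs]
    q, tau2 = dl_tau2(betas, ses)
    i2 = heterogeneity(q, len(inputs))
    if i2 > cfg.i2_random_switch:
        w = [1.0 / (s**2 + tau2) for s in ses]
        beta = sum(wi * b for wi, b in zip(w, betas)) / sum(w)
        se = 1.0 / math.sqrt(sum(w))
        model = "random"
    else:
        beta, se, _ = fixed_effects_meta(betas, ses)
        model = "fixed"
    z = beta / se
    return CombinedResult(snp_id=snp_id, inputs=labels, k=len(inputs),
                          beta=beta, se=se, z_stat=z, p=two_sided_p(z),
                          model=model, i2_across_inputs=i2, q_stat=q)


def expanded_meta(
    candidate_results: dict[str, dict[str, MetaResult | None]],
    gwas_records: Sequence[GwasSummaryRecord],
    *, config: PipelineConfig | None = None,
) -> dict[str, CombinedResult]:
    """Combine nominally significant candidate SNPs with GWAS cohort effects.

    The candidate side contributes its pooled Asian random-effects estimate
    (or the All-population pool when Caucasian exclusion is disabled); GWAS
    cohorts contribute their per-cohort betas.  SNPs with fewer than two
    usable inputs are skipped.
    """
    cfg = config or PipelineConfig()
    by_snp: dict[str, list[GwasSummaryRecord]] = {}
    for rec in gwas_records:
        by_snp.setdefault(rec.snp_id, []).append(rec)
    out: dict[str, CombinedResult] = {}
    for snp_id in gate_nominal(candidate_results, alpha=cfg.alpha):
        strata = candidate_results[snp_id]
        stratum = "Asian" if cfg.exclude_caucasian_candidates else "All"
        cand = strata.get(stratum)
        inputs: list[tuple[str, float, float]] = []
        if cand is not None and not cand.degenerate:
            inputs.append((f"candidate_{stratum}", cand.pooled_ae_random, cand.se_random))
        inputs.extend(
            (rec.cohort_id or f"gwas_{i}", rec.beta, rec.se)
            for i, rec in enumerate(by_snp.get(snp_id, ()))
        )
        if len(inputs) >= 2:
            out[snp_id] = combine_inverse_variance(inputs, snp_id=snp_id, config=cfg)
    return out
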