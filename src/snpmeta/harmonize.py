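"""Allele harmonization against a reference panel, and control-group HWE.

Published association studies report alleles on whichever strand the assay
used, and occasionally with the risk/protective labels swapped.  Before
pooling, every study effect is aligned to the reference forward strand and
oriented to the reference minor allele:

1. reported alleles match the reference pair      -> frequency-concordance check;
2. they match only the complemented pair          -> strand flip, then step 1;
3. the pair is palindromic (A/T or C/G)           -> orient by allele frequency,
   or exclude when the reference MAF is too close to 0.5 to discriminate;
4. neither orientation matches                    -> exclude as unresolved.

The frequency-concordance check flags a label switch when the study's
frequency for the reference minor allele sits near 1 - MAF instead of MAF;
the effect sign is then negated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .config import PipelineConfig
from .effects import EffectEstimate, extract_effect
from .records import COMPLEMENT, ReferenceFrequency, ReferenceTable, StudyRecord

EXCLUDED_ACTIONS = frozenset({"excluded_ambiguous", "excluded_unresolved"})


@dataclass(frozen=True)
class HarmonizedStudy:
    """An effect aligned to the reference strand and minor allele, or an exclusion."""

    study_id: str
    snp_id: str
    estimate: Optional[EffectEstimate]  # None iff excluded
    action: str   # unchanged | allele_switched | strand_flipped |
                  # strand_flipped_and_switched | excluded_ambiguous | excluded_unresolved
    effect_allele: Optional[str] = None  # reference minor allele when known
    note: str = ""

    def __post_init__(self) -> None:
        if (self.action in EXCLUDED_ACTIONS) != (self.estimate is None):
            raise ValueError("excluded records carry no estimate; included ones must")

    @property
    def excluded(self) -> bool:
        return self.action in EXCLUDED_ACTIONS


@dataclass(frozen=True)
class HweResult:
    study_id: str
    p_exact: float
    violates: bool  # p < alpha

    def __post_init__(self) -> None:
        if not 0 <= self.p_exact <= 1:
            raise ValueError(f"p must lie in [0, 1], got {self.p_exact}")


def _freq_discordant(freq: float, maf: float, cfg: PipelineConfig) -> bool:
    """True when `freq` looks like 1 - MAF rather than MAF (a label switch)."""
    return abs(freq - maf) > cfg.switch_maf_delta and abs(freq - (1 - maf)) <= cfg.switch_match_tol


def _orient(record: StudyRecord, est: EffectEstimate, ref: ReferenceFrequency,
            strand_flipped: bool) -> tuple[EffectEstimate, str, str]:
    """Map allele labels (post strand-fix) onto the reference pair.

    Returns the estimate oriented to the reference *minor* allele, so pooled
    results are comparable across studies regardless of which allele each
    study chose as allele_1.
    """
    a1 = COMPLEMENT[record.allele_1] if strand_flipped else record.allele_1
    oriented = est if a1 == ref.minor_allele else est.flipped()
    return oriented, a1, (COMPLEMENT[record.allele_2] if strand_flipped else record.allele_2)


def align_to_reference(
    record: StudyRecord,
    reference: ReferenceTable,
    population: str,
    config: PipelineConfig | None = None,
) -> HarmonizedStudy:
    """Align one study record to the reference forward strand and minor allele."""
    cfg = config or PipelineConfig()
    est = extract_effect(record, trio_se_literal=cfg.trio_se_literal,
                         ci_se_literal=cfg.ci_se_literal)
    ref = reference.lookup(record.snp_id, population)
    if ref is None:
        return HarmonizedStudy(
            study_id=record.study_id, snp_id=record.snp_id, estimate=est,
            action="unchanged", effect_allele=record.allele_1,
            note=f"{record.snp_id} absent from reference panel ({population}); not checked",
        )

    reported = frozenset((record.allele_1, record.allele_2))
    complemented = frozenset(COMPLEMENT[a] for a in reported)

    if record.is_palindromic:
        return resolve_palindromic(record, ref, cfg, est)

    if reported == ref.alleles:
        strand_flipped = False
    elif complemented == ref.alleles:
        strand_flipped = True
    else:
        return HarmonizedStudy(
            study_id=record.study_id, snp_id=record.snp_id, estimate=None,
            action="excluded_unresolved",
            note=f"alleles {record.allele_1}/{record.allele_2} match neither "
                 f"{ref.minor_allele}/{ref.major_allele} nor its complement",
        )

    oriented, a1, _ = _orient(record, est, ref, strand_flipped)
    # frequency concordance, on the reference minor allele
    f1 = record.control_freq_allele1()
    switched = False
    note = "strand flipped to forward" if strand_flipped else ""
    if f1 is not None:
        f_minor = f1 if a1 == ref.minor_allele else 1 - f1
        if _freq_discordant(f_minor, ref.maf, cfg):
            switched = True
            oriented = oriented.flipped()
            note = (note + "; " if note else "") + (
                f"reported freq {f_minor:.3f} matches 1-MAF (MAF {ref.maf:.3f}); labels switched"
            )
    if strand_flipped and switched:
        action = "strand_flipped_and_switched"
    elif strand_flipped:
        action = "strand_flipped"
    elif switched:
        action = "allele_switched"
    else:
        action = "unchanged"
    return HarmonizedStudy(study_id=record.study_id, snp_id=record.snp_id,
                           estimate=oriented, action=action,
                           effect_allele=ref.minor_allele, note=note)


def resolve_palindromic(
    record: StudyRecord,
    ref: ReferenceFrequency,
    config: PipelineConfig | None = None,
    est: EffectEstimate | None = None,
) -> HarmonizedStudy:
    """Orient an A/T or C/G study by allele frequency, or exclude it.

    Strand cannot distinguish the two alleles of a palindromic SNP, so the
    only usable signal is which side of 0.5 the study's allele frequency
    falls on.  When the reference MAF lies inside the ambiguity window, or the
    study reports no frequency, the record is excluded.
    """
    cfg = config or PipelineConfig()
    if est is None:
        est = extract_effect(record, trio_se_literal=cfg.trio_se_literal,
                             ci_se_literal=cfg.ci_se_literal)
    base = dict(study_id=record.study_id, snp_id=record.snp_id)
    if frozenset((record.allele_1, record.allele_2)) != ref.alleles:
        return HarmonizedStudy(
            estimate=None, action="excluded_unresolved",
            note=f"palindromic alleles {record.allele_1}/{record.allele_2} do not "
                 f"match reference {ref.minor_allele}/{ref.major_allele}", **base)
    if cfg.palindromic_low <= ref.maf <= cfg.palindromic_high:
        return HarmonizedStudy(
            estimate=None, action="excluded_ambiguous",
            note=f"palindromic with reference MAF {ref.maf:.3f} inside "
                 f"[{cfg.palindromic_low}, {cfg.palindromic_high}]", **base)
    f1 = record.control_freq_allele1()
    if f1 is None:
        return HarmonizedStudy(
            estimate=None, action="excluded_ambiguous",
            note="palindromic with no reported allele frequency", **base)
    # After complementing, a palindromic pair maps onto itself, so compare the
    # study's frequency for the allele *labelled* as the reference minor.
    oriented, a1, _ = _orient(record, est, ref, strand_flipped=False)
    f_minor = f1 if record.allele_1 == ref.minor_allele else 1 - f1
    if (f_minor < 0.5) == (ref.maf < 0.5):
        action = "unchanged"
    else:
        oriented = oriented.flipped()
        action = "allele_switched"
    return HarmonizedStudy(estimate=oriented, action=action,
                           effect_allele=ref.minor_allele,
                           note=f"palindromic oriented by frequency ({f_minor:.3f} vs MAF {ref.maf:.3f})",
                           **base)


def hwe_exact_test(ctrl_aa: int, ctrl_het: int, ctrl_bb: int) -> float:
    """Exact Hardy–Weinberg test on control genotype counts.

    Conditional on the observed allele counts, the number of heterozygotes
    n_Aa follows a known distribution under HWE; the p-value sums the
    probabilities of all heterozygote configurations no more probable than
    the observed one.
    """
    n = ctrl_aa + ctrl_het + ctrl_bb
    if n == 0:
        raise ValueError("no control genotypes to test")
    n_a = 2 * ctrl_aa + ctrl_het  # copies of allele 1
    # support: n_het has the parity of n_a, between max residue and min(n_a, 2n - n_a)
    n_b = 2 * n - n_a
    max_het = min(n_a, n_b)
    hets = range(max_het % 2, max_het + 1, 2)
    # log P(n_het | n, n_a) up to a constant:  2^het * n! / (aa! het! bb!)
    logp = []
    for h in hets:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        lp = (h * math.log(2) + math.lgamma(n + 1)
              - math.lgamma(aa + 1) - math.lgamma(h + 1) - math.lgamma(bb + 1))
        logp.append(lp)
    m = max(logp)
    probs = [math.exp(lp - m) for lp in logp]
    total = sum(probs)
    obs = {h: pr for h, pr in zip(hets, probs)}[ctrl_het]
    p = sum(pr for pr in probs if pr <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_chisq_test(ctrl_aa: int, ctrl_het: int, ctrl_bb: int) -> float:
    """One-df chi-square HWE test (config alternative to the exact test)."""
    n = ctrl_aa + ctrl_het + ctrl_bb
    if n == 0:
        raise ValueError("no control genotypes to test")
    p1 = (2 * ctrl_aa + ctrl_het) / (2 * n)
    exp = (n * p1**2, 2 * n * p1 * (1 - p1), n * (1 - p1) ** 2)
    if any(e == 0 for e in exp):
        return 1.0
    chi2 = sum((o - e) ** 2 / e for o, e in zip((ctrl_aa, ctrl_het, ctrl_bb), exp))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test(record: StudyRecord, config: PipelineConfig | None = None) -> Optional[HweResult]:
    """HWE check on a study's control genotypes; None when not testable.

    Only genotype payloads can be tested — allele counts and summary
    statistics carry no genotype-level information.
    """
    cfg = config or PipelineConfig()
    g = record.genotype_counts
    if g is None:
        return None
    test = hwe_exact_test if cfg.hwe_method == "exact" else hwe_chisq_test
    p = test(g.ctrl_aa_hom, g.ctrl_het, g.ctrl_bb_hom)
    return HweResult(study_id=record.study_id, p_exact=p, violates=p < cfg.hwe_alpha)


def eligibility_filter(
    harmonized: Sequence[HarmonizedStudy], *, min_studies: int = 4,
) -> tuple[list[HarmonizedStudy], bool]:
    """Non-excluded studies for one SNP x population, and whether the stratum
    meets the minimum-study eligibility rule."""
    usable = [h for h in harmonized if not h.excluded]
    return usable, len(usable) >= min_studies
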