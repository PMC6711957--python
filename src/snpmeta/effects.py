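"""Per-study allelic effect extraction.

Each study contributes one allelic effect (AE, the natural-log odds ratio for
carrying allele_1) and its standard error (seAE).  Four extraction routes are
supported, in decreasing order of information content:

* allele/genotype counts — Woolf log-OR with its large-sample SE,
* a reported OR with a 95% CI — SE from the log-scale CI width,
* a reported OR with a two-sided p — SE back-calculated from the normal
  quantile via a closed-form approximation,
* trio transmission counts — log transmission ratio (Kazeem–Farrall).

Zero cells get the Haldane–Anscombe +0.5 continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .records import AlleleCounts, StudyRecord, ValidationError

Z_95 = 1.959963984540054  # Phi^-1(0.975)


class ExtractionError(ValueError):
    """A payload cannot yield a usable (AE, seAE) pair."""


@dataclass(frozen=True)
class EffectEstimate:
    """Allelic effect (log OR) and standard error, with extraction provenance.

    ``table`` retains the allele 2x2 counts (case_a, case_b, ctrl_a, ctrl_b)
    when the counts route was used; the Harbord score test needs it.
    """

    snp_id: str
    study_id: str
    ae: float
    se_ae: float
    route: str  # allele_counts | genotype_counts | p_based | ci_based | trio
    ancestry: str = "Other"
    design: str = "case_control"
    k_cases: Optional[int] = None
    k_controls: Optional[int] = None
    table: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if not self.se_ae > 0 or not math.isfinite(self.se_ae):
            raise ValidationError(f"se_ae must be positive and finite, got {self.se_ae}")
        if not math.isfinite(self.ae):
            raise ValidationError(f"ae must be finite, got {self.ae}")

    def flipped(self) -> "EffectEstimate":
        """The same evidence expressed for the other allele."""
        table = None
        if self.table is not None:
            a1, b1, a0, b0 = self.table
            table = (b1, a1, b0, a0)
        return EffectEstimate(
            snp_id=self.snp_id, study_id=self.study_id, ae=-self.ae, se_ae=self.se_ae,
            route=self.route, ancestry=self.ancestry, design=self.design,
            k_cases=self.k_cases, k_controls=self.k_controls, table=table,
        )

    @property
    def or_value(self) -> float:
        return math.exp(self.ae)


def genotype_to_allele_counts(
    case_aa: int, case_het: int, case_bb: int,
    ctrl_aa: int, ctrl_het: int, ctrl_bb: int,
) -> tuple[int, int, int, int]:
    """Collapse genotype counts to allele counts: C_A = 2*AA + Aa, C_a = 2*aa + Aa."""
    for v in (case_aa, case_het, case_bb, ctrl_aa, ctrl_het, ctrl_bb):
        if v < 0:
            raise ValidationError("genotype counts must be non-negative")
    return (
        2 * case_aa + case_het,
        2 * case_bb + case_het,
        2 * ctrl_aa + ctrl_het,
        2 * ctrl_bb + ctrl_het,
    )


def _corrected(cells: tuple[float, float, float, float]) -> tuple[float, ...]:
    """Haldane–Anscombe: add 0.5 to every cell if any cell is zero."""
    if any(c == 0 for c in cells):
        return tuple(c + 0.5 for c in cells)
    return cells


def effect_from_allele_counts(
    case_a: int, case_b: int, ctrl_a: int, ctrl_b: int,
    *, snp_id: str = "", study_id: str = "", route: str = "allele_counts",
    ancestry: str = "Other",
) -> EffectEstimate:
    """Woolf estimate of the allelic log OR for allele `a` from the 2x2 table.

    ae = log[(case_a * ctrl_b) / (case_b * ctrl_a)];
    se = sqrt(sum of reciprocal cells).  Cells are continuity-corrected
    (+0.5 everywhere) when any cell is zero.
    """
    if (case_a + case_b) == 0 or (ctrl_a + ctrl_b) == 0:
        raise ExtractionError("a study arm has zero total alleles")
    a1, b1, a0, b0 = _corrected((case_a, case_b, ctrl_a, ctrl_b))
    ae = math.log((a1 * b0) / (b1 * a0))
    se = math.sqrt(1 / a1 + 1 / b1 + 1 / a0 + 1 / b0)
    return EffectEstimate(
        snp_id=snp_id, study_id=study_id, ae=ae, se_ae=se, route=route,
        ancestry=ancestry,
        k_cases=(case_a + case_b) // 2, k_controls=(ctrl_a + ctrl_b) // 2,
        table=(float(case_a), float(case_b), float(ctrl_a), float(ctrl_b)),
    )


def pvalue_denominator(p: float) -> float:
    """Closed-form approximation to Phi^-1(1 - p/2) used to back-calculate SE.

    Accurate to well under 0.5% for two-sided p between 1e-8 and 0.5.
    """
    if not 0 < p < 1:
        raise ExtractionError(f"p must lie in (0, 1), got {p}")
    return -0.862 + math.sqrt(0.743 - 2.404 * math.log(p))


def effect_from_pvalue(
    or_value: float, p: float,
    *, snp_id: str = "", study_id: str = "", ancestry: str = "Other",
) -> EffectEstimate:
    """Back-calculate seAE from a reported OR and its two-sided p-value.

    se = |log OR| / z(p) with z(p) the approximate normal quantile above.
    OR = 1 is degenerate for this route (zero effect with a finite p carries
    no scale information) and raises, so the caller can fall back or exclude.
    """
    if or_value <= 0:
        raise ExtractionError(f"OR must be positive, got {or_value}")
    ae = math.log(or_value)
    if ae == 0.0:
        raise ExtractionError(
            "OR = 1 with the p-based route leaves the standard error undefined; "
            "use a confidence interval or counts, or exclude the study"
        )
    se = abs(ae) / pvalue_denominator(p)
    return EffectEstimate(snp_id=snp_id, study_id=study_id, ae=ae, se_ae=se,
                          route="p_based", ancestry=ancestry)


def effect_from_ci(
    or_value: float, ci_low: float, ci_up: float,
    *, snp_id: str = "", study_id: str = "", ancestry: str = "Other",
    literal: bool = False,
) -> EffectEstimate:
    """seAE from a reported 95% CI: (log CI_up - log CI_low) / (2 * 1.96).

    ``literal=True`` instead reports CI_up - OR on the odds-ratio scale — an
    audit/compatibility mode reproducing a published formula that mixes the OR
    and log-OR scales; it is never the default.
    """
    if not (0 < ci_low < or_value < ci_up):
        raise ExtractionError(
            f"CI must satisfy 0 < low < OR < up, got ({ci_low}, {or_value}, {ci_up})"
        )
    ae = math.log(or_value)
    if literal:
        se = ci_up - or_value
    else:
        se = (math.log(ci_up) - math.log(ci_low)) / (2 * Z_95)
    return EffectEstimate(snp_id=snp_id, study_id=study_id, ae=ae, se_ae=se,
                          route="ci_based", ancestry=ancestry)


def effect_from_trio(
    transmitted: int, not_transmitted: int,
    *, snp_id: str = "", study_id: str = "", ancestry: str = "Other",
    literal_se: bool = False,
) -> EffectEstimate:
    """Log transmission ratio from heterozygous-parent trios.

    ae = log(C_T / C_N); se = sqrt(1/C_T + 1/C_N), the Kazeem–Farrall
    large-sample SE of the log relative risk.  ``literal_se=True`` drops the
    square root (compatibility mode for a published misprint).  Zero counts
    get the +0.5 correction.
    """
    if transmitted == 0 and not_transmitted == 0:
        raise ExtractionError("trio study with no transmissions in either direction")
    t, n = _corrected((transmitted, not_transmitted))
    ae = math.log(t / n)
    var = 1 / t + 1 / n
    se = var if literal_se else math.sqrt(var)
    return EffectEstimate(snp_id=snp_id, study_id=study_id, ae=ae, se_ae=se,
                          route="trio", ancestry=ancestry, design="family",
                          k_cases=int(transmitted + not_transmitted))


def select_data_source(record: StudyRecord) -> str:
    """Which payload the extraction uses, by information-content priority.

    Family studies always use trio counts.  Case-control studies prefer
    genotype counts, then allele counts, then statistics (CI over p).
    """
    if record.design == "family":
        return "trio"
    if record.genotype_counts is not None:
        return "genotype_counts"
    if record.allele_counts is not None:
        return "allele_counts"
    if record.statistics is not None:
        return "ci_based" if record.statistics.ci_low is not None else "p_based"
    raise ExtractionError(f"study {record.study_id}: no usable payload")


def extract_effect(
    record: StudyRecord,
    *, trio_se_literal: bool = False, ci_se_literal: bool = False,
) -> EffectEstimate:
    """Extract (AE, seAE) for allele_1 of ``record`` via the preferred route."""
    route = select_data_source(record)
    kw = dict(snp_id=record.snp_id, study_id=record.study_id, ancestry=record.ancestry)
    if route == "trio":
        tc = record.trio_counts
        return effect_from_trio(tc.transmitted, tc.not_transmitted,
                                literal_se=trio_se_literal, **kw)
    if route == "genotype_counts":
        ac = record.genotype_counts.to_allele_counts()
        est = effect_from_allele_counts(ac.case_a, ac.case_b, ac.ctrl_a, ac.ctrl_b,
                                        route="genotype_counts", **kw)
        return est
    if route == "allele_counts":
        ac: AlleleCounts = record.allele_counts
        return effect_from_allele_counts(ac.case_a, ac.case_b, ac.ctrl_a, ac.ctrl_b, **kw)
    st = record.statistics
    if route == "ci_based":
        return effect_from_ci(st.or_value, st.ci_low, st.ci_up,
                              literal=ci_se_literal, **kw)
    return effect_from_pvalue(st.or_value, st.p_value, **kw)
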