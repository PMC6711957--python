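"""Domain records: per-study evidence, reference allele frequencies, GWAS rows.

A :class:`StudyRecord` holds one published study's evidence for one SNP.  A
study may report any subset of four payloads — case/control genotype counts,
case/control allele counts, summary statistics (OR with p or 95% CI), or trio
transmission counts — and downstream extraction picks the most informative one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ANCESTRIES = ("Asian", "Caucasian", "Other")
DESIGNS = ("case_control", "family")
POPULATIONS = ("AFR", "EAS", "EUR", "SAS")


class ValidationError(ValueError):
    """A record violates its schema invariants."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Case and control genotype counts: AA/Aa/aa where A is allele_1."""

    case_aa_hom: int   # allele_1 homozygotes among cases (AA)
    case_het: int
    case_bb_hom: int   # allele_2 homozygotes (aa)
    ctrl_aa_hom: int
    ctrl_het: int
    ctrl_bb_hom: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"genotype count {name}={v!r} must be a non-negative integer")

    def to_allele_counts(self) -> "AlleleCounts":
        return AlleleCounts(
            case_a=2 * self.case_aa_hom + self.case_het,
            case_b=2 * self.case_bb_hom + self.case_het,
            ctrl_a=2 * self.ctrl_aa_hom + self.ctrl_het,
            ctrl_b=2 * self.ctrl_bb_hom + self.ctrl_het,
        )

    @property
    def n_cases(self) -> int:
        return self.case_aa_hom + self.case_het + self.case_bb_hom

    @property
    def n_controls(self) -> int:
        return self.ctrl_aa_hom + self.ctrl_het + self.ctrl_bb_hom


@dataclass(frozen=True)
class AlleleCounts:
    """Allele-level 2x2 table; `a` is allele_1, `b` is allele_2."""

    case_a: int
    case_b: int
    ctrl_a: int
    ctrl_b: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"allele count {name}={v!r} must be a non-negative integer")

    @property
    def control_freq_allele1(self) -> Optional[float]:
        tot = self.ctrl_a + self.ctrl_b
        return self.ctrl_a / tot if tot else None


@dataclass(frozen=True)
class Statistics:
    """Reported association statistics: OR for allele_1, with p and/or 95% CI."""

    or_value: float
    p_value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_up: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.or_value > 0 or not math.isfinite(self.or_value):
            raise ValidationError(f"OR must be a positive finite number, got {self.or_value}")
        if self.p_value is None and self.ci_low is None:
            raise ValidationError("statistics payload needs a p-value or a confidence interval")
        if self.p_value is not None and not 0 < self.p_value < 1:
            raise ValidationError(f"p-value must lie in (0, 1), got {self.p_value}")
        if (self.ci_low is None) != (self.ci_up is None):
            raise ValidationError("confidence interval needs both bounds")
        if self.ci_low is not None:
            if not 0 < self.ci_low < self.or_value < self.ci_up:
                raise ValidationError(
                    f"CI must satisfy 0 < low < OR < up, got ({self.ci_low}, {self.or_value}, {self.ci_up})"
                )


@dataclass(frozen=True)
class TrioCounts:
    """Transmissions / non-transmissions of allele_1 from heterozygous parents."""

    transmitted: int
    not_transmitted: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"trio count {name}={v!r} must be a non-negative integer")
        if self.transmitted == 0 and self.not_transmitted == 0:
            raise ValidationError("trio payload with zero transmissions and non-transmissions")


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    snp_id: str
    ancestry: str
    design: str
    allele_1: str
    allele_2: str
    pubmed_id: Optional[str] = None
    genotype_counts: Optional[GenotypeCounts] = None
    allele_counts: Optional[AlleleCounts] = None
    statistics: Optional[Statistics] = None
    trio_counts: Optional[TrioCounts] = None
    reported_freq_allele1: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ancestry not in ANCESTRIES:
            raise ValidationError(f"ancestry must be one of {ANCESTRIES}, got {self.ancestry!r}")
        if self.design not in DESIGNS:
            raise ValidationError(f"design must be one of {DESIGNS}, got {self.design!r}")
        for a in (self.allele_1, self.allele_2):
            if a not in NUCLEOTIDES:
                raise ValidationError(f"allele {a!r} is not one of A/C/G/T")
        if self.allele_1 == self.allele_2:
            raise ValidationError("allele_1 and allele_2 must differ")
        if not any((self.genotype_counts, self.allele_counts, self.statistics, self.trio_counts)):
            raise ValidationError("record carries no payload")
        if self.trio_counts is not None and self.design != "family":
            raise ValidationError("trio counts require a family design")
        if self.design == "family" and self.trio_counts is None:
            raise ValidationError("family design requires trio counts")
        if self.reported_freq_allele1 is not None and not 0 <= self.reported_freq_allele1 <= 1:
            raise ValidationError(
                f"reported_freq_allele1 must lie in [0, 1], got {self.reported_freq_allele1}"
            )
        if self.genotype_counts is not None and self.allele_counts is not None:
            if self.genotype_counts.to_allele_counts() != self.allele_counts:
                raise ValidationError("genotype counts and allele counts are inconsistent")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.allele_1] == self.allele_2

    def control_freq_allele1(self) -> Optional[float]:
        """Control-group frequency of allele_1: reported if given, else from counts."""
        if self.reported_freq_allele1 is not None:
            return self.reported_freq_allele1
        if self.genotype_counts is not None:
            return self.genotype_counts.to_allele_counts().control_freq_allele1
        if self.allele_counts is not None:
            return self.allele_counts.control_freq_allele1
        return None


@dataclass(frozen=True)
class ReferenceFrequency:
    """Reference-panel minor-allele frequency for one SNP in one population."""

    snp_id: str
    population: str
    minor_allele: str
    maf: float
    major_allele: str

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(f"population must be one of {POPULATIONS}, got {self.population!r}")
        for a in (self.minor_allele, self.major_allele):
            if a not in NUCLEOTIDES:
                raise ValidationError(f"allele {a!r} is not one of A/C/G/T")
        if self.minor_allele == self.major_allele:
            raise ValidationError("minor and major allele must differ")
        if not 0 <= self.maf <= 0.5:
            raise ValidationError(f"MAF must lie in [0, 0.5], got {self.maf}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.minor_allele, self.major_allele))


class ReferenceTable:
    """Lookup of reference frequencies keyed by (snp_id, population).

    Absent entries return ``None`` — an explicit "unknown" marker — rather
    than raising, because studies of SNPs missing from the panel are carried
    through harmonization unchanged with a warning note.
    """

    def __init__(self, entries: list[ReferenceFrequency] | None = None):
        self._table: dict[tuple[str, str], ReferenceFrequency] = {}
        for e in entries or []:
            self.add(e)

    def add(self, entry: ReferenceFrequency) -> None:
        self._table[(entry.snp_id, entry.population)] = entry

    def lookup(self, snp_id: str, population: str) -> Optional[ReferenceFrequency]:
        return self._table.get((snp_id, population))

    def __len__(self) -> int:
        return len(self._table)

    def __iter__(self):
        return iter(self._table.values())


@dataclass(frozen=True)
class GwasSummaryRecord:
    """One SNP row of a GWAS summary-statistics file (effect on the log-OR scale)."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: Optional[float] = None
    n: Optional[int] = None
    cohort_id: str = ""
    ancestry: str = "Other"
    from_or_scale: bool = False   # provenance: True when the file reported an OR

    def __post_init__(self) -> None:
        for a in (self.effect_allele, self.other_allele):
            if a not in NUCLEOTIDES:
                raise ValidationError(f"allele {a!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValidationError("effect and other allele must differ")
        if not self.se > 0:
            raise ValidationError(f"SE must be positive, got {self.se}")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele
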