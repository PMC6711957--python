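"""Tabular I/O: study tables, reference frequencies, GWAS summaries, results.

All formats are plain TSV with a header row.  Reading is *total*: every input
row is either turned into a validated record or reported as a located
:class:`RowError` (row number + reason); nothing is silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .records import (AlleleCounts, GenotypeCounts, GwasSummaryRecord,
                      ReferenceFrequency, ReferenceTable, Statistics,
                      StudyRecord, TrioCounts, ValidationError)

STUDY_COLUMNS = [
    "study_id", "pubmed_id", "snp_id", "ancestry", "design", "allele1", "allele2",
    "case_AA", "case_Aa", "case_aa", "ctrl_AA", "ctrl_Aa", "ctrl_aa",
    "case_A", "case_a", "ctrl_A", "ctrl_a",
    "or_value", "p_value", "ci_low", "ci_up",
    "trio_T", "trio_N", "reported_freq_allele1",
]
REFERENCE_COLUMNS = ["snp_id", "population", "minor_allele", "maf", "major_allele"]
GWAS_COLUMNS = ["SNP", "A1", "A2", "BETA", "OR", "SE", "P", "N"]  # BETA or OR required

RESULT_COLUMNS = [
    "snp_id", "population", "model", "k", "n_cases", "n_controls",
    "pooled_ae", "se", "or_value", "ci_low", "ci_up", "p_value",
    "q_stat", "i2", "tau2",
]


class SchemaError(ValueError):
    """The file is missing mandatory columns."""


@dataclass(frozen=True)
class RowError:
    row: int        # 1-based data-row number (header not counted)
    reason: str

    def __str__(self) -> str:
        return f"row {self.row}: {self.reason}"


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def _opt_int(v, name: str) -> Optional[int]:
    if _blank(v):
        return None
    s = str(v).strip()
    try:
        f = float(s)
    except ValueError:
        raise ValidationError(f"{name}={s!r} is not numeric") from None
    if f != int(f):
        raise ValidationError(f"{name}={s!r} is not an integer count")
    return int(f)


def _opt_float(v, name: str) -> Optional[float]:
    if _blank(v):
        return None
    try:
        return float(str(v).strip())
    except ValueError:
        raise ValidationError(f"{name}={v!r} is not numeric") from None


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")


def _record_from_row(row: pd.Series) -> StudyRecord:
    geno_vals = [_opt_int(row[c], c) for c in
                 ("case_AA", "case_Aa", "case_aa", "ctrl_AA", "ctrl_Aa", "ctrl_aa")]
    allele_vals = [_opt_int(row[c], c) for c in ("case_A", "case_a", "ctrl_A", "ctrl_a")]
    genotype = None
    if any(v is not None for v in geno_vals):
        if any(v is None for v in geno_vals):
            raise ValidationError("genotype payload must fill all six count cells")
        genotype = GenotypeCounts(*geno_vals)
    alleles = None
    if any(v is not None for v in allele_vals):
        if any(v is None for v in allele_vals):
            raise ValidationError("allele payload must fill all four count cells")
        alleles = AlleleCounts(*allele_vals)
    stats = None
    or_value = _opt_float(row["or_value"], "or_value")
    if or_value is not None:
        stats = Statistics(
            or_value=or_value,
            p_value=_opt_float(row["p_value"], "p_value"),
            ci_low=_opt_float(row["ci_low"], "ci_low"),
            ci_up=_opt_float(row["ci_up"], "ci_up"),
        )
    trio = None
    t = _opt_int(row["trio_T"], "trio_T")
    n = _opt_int(row["trio_N"], "trio_N")
    if (t is None) != (n is None):
        raise ValidationError("trio payload needs both trio_T and trio_N")
    if t is not None:
        trio = TrioCounts(t, n)
    return StudyRecord(
        study_id=str(row["study_id"]).strip(),
        pubmed_id=None if _blank(row["pubmed_id"]) else str(row["pubmed_id"]).strip(),
        snp_id=str(row["snp_id"]).strip(),
        ancestry=str(row["ancestry"]).strip(),
        design=str(row["design"]).strip(),
        allele_1=str(row["allele1"]).strip().upper(),
        allele_2=str(row["allele2"]).strip().upper(),
        genotype_counts=genotype, allele_counts=alleles,
        statistics=stats, trio_counts=trio,
        reported_freq_allele1=_opt_float(row["reported_freq_allele1"],
                                         "reported_freq_allele1"),
    )


def read_study_table(path: str | Path) -> tuple[list[StudyRecord], list[RowError]]:
    """Read a per-study TSV; returns (valid records, located row errors)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, STUDY_COLUMNS, path)
    records, errors = [], []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_record_from_row(row))
        except ValidationError as exc:
            errors.append(RowError(row=i, reason=str(exc)))
    return records, errors


def write_study_table(records: list[StudyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {c: "" for c in STUDY_COLUMNS}
        row.update(study_id=r.study_id, pubmed_id=r.pubmed_id or "",
                   snp_id=r.snp_id, ancestry=r.ancestry, design=r.design,
                   allele1=r.allele_1, allele2=r.allele_2)
        if r.genotype_counts is not None:
            g = r.genotype_counts
            row.update(case_AA=g.case_aa_hom, case_Aa=g.case_het, case_aa=g.case_bb_hom,
                       ctrl_AA=g.ctrl_aa_hom, ctrl_Aa=g.ctrl_het, ctrl_aa=g.ctrl_bb_hom)
        if r.allele_counts is not None:
            a = r.allele_counts
            row.update(case_A=a.case_a, case_a=a.case_b, ctrl_A=a.ctrl_a, ctrl_a=a.ctrl_b)
        if r.statistics is not None:
            s = r.statistics
            row["or_value"] = repr(float(s.or_value))
            if s.p_value is not None:
                row["p_value"] = repr(float(s.p_value))
            if s.ci_low is not None:
                row.update(ci_low=repr(float(s.ci_low)), ci_up=repr(float(s.ci_up)))
        if r.trio_counts is not None:
            row.update(trio_T=r.trio_counts.transmitted, trio_N=r.trio_counts.not_transmitted)
        if r.reported_freq_allele1 is not None:
            row["reported_freq_allele1"] = repr(float(r.reported_freq_allele1))
        rows.append(row)
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reference_frequencies(path: str | Path) -> tuple[ReferenceTable, list[RowError]]:
    """Read the reference MAF table into a (snp, population) lookup."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, REFERENCE_COLUMNS, path)
    table, errors = ReferenceTable(), []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            maf = _opt_float(row["maf"], "maf")
            if maf is None:
                raise ValidationError("maf cell is empty")
            table.add(ReferenceFrequency(
                snp_id=str(row["snp_id"]).strip(),
                population=str(row["population"]).strip(),
                minor_allele=str(row["minor_allele"]).strip().upper(),
                maf=maf,
                major_allele=str(row["major_allele"]).strip().upper(),
            ))
        except ValidationError as exc:
            errors.append(RowError(row=i, reason=str(exc)))
    return table, errors


def write_reference_frequencies(table: ReferenceTable, path: str | Path) -> None:
    rows = [
        dict(snp_id=e.snp_id, population=e.population, minor_allele=e.minor_allele,
             maf=repr(float(e.maf)), major_allele=e.major_allele)
        for e in table
    ]
    pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gwas_summary(
    path: str | Path, *, cohort_id: str = "", ancestry: str = "Other",
) -> tuple[list[GwasSummaryRecord], list[RowError]]:
    """Read a GWAS summary file (SNP, A1, A2, BETA|OR, SE, P, N).

    Effects reported as ORs are moved to the log scale at read time; the
    record's ``from_or_scale`` flag keeps that provenance.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    _require_columns(df, ["SNP", "A1", "A2", "SE"], path)
    if "BETA" not in df.columns and "OR" not in df.columns:
        raise SchemaError(f"{path}: needs a BETA or an OR column")
    records, errors = [], []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            se = _opt_float(row["SE"], "SE")
            if se is None or se <= 0:
                raise ValidationError(f"SE must be positive, got {row['SE']!r}")
            from_or = False
            if "BETA" in df.columns and not _blank(row["BETA"]):
                beta = _opt_float(row["BETA"], "BETA")
            elif "OR" in df.columns and not _blank(row.get("OR")):
                or_value = _opt_float(row["OR"], "OR")
                if or_value is None or or_value <= 0:
                    raise ValidationError(f"OR must be positive, got {row.get('OR')!r}")
                beta = math.log(or_value)
                from_or = True
            else:
                raise ValidationError("row has neither BETA nor OR")
            records.append(GwasSummaryRecord(
                snp_id=str(row["SNP"]).strip(),
                effect_allele=str(row["A1"]).strip().upper(),
                other_allele=str(row["A2"]).strip().upper(),
                beta=beta, se=se,
                p=_opt_float(row["P"], "P") if "P" in df.columns else None,
                n=_opt_int(row["N"], "N") if "N" in df.columns else None,
                cohort_id=cohort_id, ancestry=ancestry, from_or_scale=from_or,
            ))
        except ValidationError as exc:
            errors.append(RowError(row=i, reason=str(exc)))
    return records, errors


def write_gwas_summary(records: list[GwasSummaryRecord], path: str | Path) -> None:
    rows = [
        dict(SNP=r.snp_id, A1=r.effect_allele, A2=r.other_allele, BETA=repr(float(r.beta)),
             SE=repr(float(r.se)), P="" if r.p is None else repr(float(r.p)),
             N="" if r.n is None else r.n)
        for r in records
    ]
    pd.DataFrame(rows, columns=["SNP", "A1", "A2", "BETA", "SE", "P", "N"]).to_csv(
        path, sep="\t", index=False)


def write_results(rows: list[dict], out_prefix: str | Path,
                  diagnostics: dict | None = None) -> tuple[Path, Path]:
    """Write the result table as TSV plus a JSON mirror with diagnostics.

    ``rows`` are one dict per SNP x population x model with the
    ``RESULT_COLUMNS`` keys; ``diagnostics`` is an arbitrary JSON-serialisable
    per-study payload appended to the JSON report.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    payload = {"results": rows, "diagnostics": diagnostics or {}}
    json_path.write_text(json.dumps(payload, indent=1, default=str))
    return tsv_path, json_path


def read_results(tsv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")
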