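"""Data model and CSV I/O for study-level case-control genotype counts.

A *study record* is one row of a genotype-count meta-analysis input table:
identifying labels (author, year, origin), stratification labels (phenotype,
ethnicity, source of controls), and the six genotype counts (three per arm).
Genotype columns are always ordered effect-allele homozygote, heterozygote,
other-allele homozygote, so the same schema serves variants with different
allele labels (for rs1333049 the effect allele is C; for rs4977574 it is G).

The packaged fixture ``data/table1_cdkn2b_as1.csv`` holds the 50 case-control
comparisons (33 for rs1333049, 17 for rs4977574) of the CDKN2B-AS1 /
coronary-heart-disease literature, transcribed from the published study
characteristics table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "StudySet",
    "SchemaError",
    "read_studies",
    "write_studies",
    "validate_study",
    "totals",
    "load_table1",
    "EFFECT_ALLELES",
    "ETHNICITIES",
    "PHENOTYPES",
    "CONTROL_SOURCES",
    "TABLE1_FIXTURE",
    "TABLE2_REFERENCE",
]

#: effect allele per supported variant (the allele whose dose the odds model counts)
EFFECT_ALLELES = {"rs1333049": ("C", "G"), "rs4977574": ("G", "A")}

ETHNICITIES = ("West Asian", "East Asian", "Caucasian", "African")
PHENOTYPES = ("CAD", "MI")
CONTROL_SOURCES = ("HB", "PB", "NA")

CSV_COLUMNS = [
    "study_id", "author", "year", "origin", "variant", "phenotype",
    "ethnicity", "control_source",
    "case_hom_effect", "case_het", "case_hom_other",
    "ctrl_hom_effect", "ctrl_het", "ctrl_hom_other",
    "method",
]

COUNT_COLUMNS = CSV_COLUMNS[8:14]

TABLE1_FIXTURE = "table1_cdkn2b_as1.csv"
TABLE2_REFERENCE = "table2_reference.csv"


class SchemaError(ValueError):
    """Input file does not conform to the study CSV schema."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm: (effect-hom, het, other-hom) persons."""

    hom_effect: int
    het: int
    hom_other: int

    # Negative counts are rejected at I/O time and flagged by validate_study,
    # so that a bad in-memory record can still be inspected rather than only
    # raising at construction.
    def __post_init__(self) -> None:
        for name in ("hom_effect", "het", "hom_other"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")

    def total(self) -> int:
        return self.hom_effect + self.het + self.hom_other

    def effect_allele_count(self) -> int:
        return 2 * self.hom_effect + self.het

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.hom_effect, self.het, self.hom_other)


@dataclass(frozen=True)
class StudyRecord:
    """One study-variant row of the input table."""

    study_id: str
    author: str
    year: int
    origin: str
    variant: str
    phenotype: str
    ethnicity: str
    control_source: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    method: str = ""
    #: per-arm sample sizes as printed in the source, when stated separately
    declared_n_cases: Optional[int] = None
    declared_n_controls: Optional[int] = None

    @property
    def effect_allele(self) -> str:
        return EFFECT_ALLELES.get(self.variant, ("effect", "other"))[0]

    def n_cases(self) -> int:
        return self.cases.total()

    def n_controls(self) -> int:
        return self.controls.total()


@dataclass(frozen=True)
class StudySet:
    """An ordered, uniquely-labelled collection of study records."""

    records: tuple[StudyRecord, ...]
    variant: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate study_id(s): {dupes}")
        if self.variant is not None:
            stray = [r.study_id for r in self.records if r.variant != self.variant]
            if stray:
                raise ValueError(
                    f"records not matching variant {self.variant}: {stray}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, key: int) -> StudyRecord:
        return self.records[key]

    def filter(self, **labels: str) -> "StudySet":
        """Subset on equality of label fields, e.g. ``filter(ethnicity="East Asian")``."""
        recs = self.records
        variant = self.variant
        for name, value in labels.items():
            recs = tuple(r for r in recs if getattr(r, name) == value)
            if name == "variant":
                variant = value
        return StudySet(recs, variant=variant)

    def drop(self, study_id: str) -> "StudySet":
        recs = tuple(r for r in self.records if r.study_id != study_id)
        if len(recs) == len(self.records):
            raise KeyError(study_id)
        return StudySet(recs, variant=self.variant)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "study_id": r.study_id, "author": r.author, "year": r.year,
                "origin": r.origin, "variant": r.variant,
                "phenotype": r.phenotype, "ethnicity": r.ethnicity,
                "control_source": r.control_source,
                "case_hom_effect": r.cases.hom_effect,
                "case_het": r.cases.het,
                "case_hom_other": r.cases.hom_other,
                "ctrl_hom_effect": r.controls.hom_effect,
                "ctrl_het": r.controls.het,
                "ctrl_hom_other": r.controls.hom_other,
                "method": r.method,
            })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _record_from_row(row: pd.Series, index: int) -> StudyRecord:
    counts = {}
    for col in COUNT_COLUMNS:
        raw = row[col]
        try:
            v = int(raw)
        except (TypeError, ValueError):
            raise SchemaError(
                f"row {index} ({row.get('study_id', '?')}): "
                f"non-integer count in column {col!r}: {raw!r}"
            ) from None
        if float(raw) != v:
            raise SchemaError(
                f"row {index} ({row.get('study_id', '?')}): "
                f"non-integer count in column {col!r}: {raw!r}"
            )
        if v < 0:
            raise ValueError(
                f"row {index} ({row.get('study_id', '?')}): "
                f"negative count in column {col!r}: {v}"
            )
        counts[col] = v
    return StudyRecord(
        study_id=str(row["study_id"]),
        author=str(row["author"]),
        year=int(row["year"]),
        origin=str(row["origin"]),
        variant=str(row["variant"]),
        phenotype=str(row["phenotype"]),
        ethnicity=str(row["ethnicity"]),
        control_source=str(row["control_source"]),
        cases=GenotypeCounts(
            counts["case_hom_effect"], counts["case_het"], counts["case_hom_other"]
        ),
        controls=GenotypeCounts(
            counts["ctrl_hom_effect"], counts["ctrl_het"], counts["ctrl_hom_other"]
        ),
        method=str(row.get("method", "")),
    )


def read_studies(path: str | Path, variant: Optional[str] = None) -> StudySet:
    """Read a study CSV, validate it, and optionally keep one variant only.

    Raises :class:`SchemaError` for a missing column or a non-integer count
    (naming the offending column/row) and :class:`ValueError` for negative
    counts or duplicate study ids.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = tuple(_record_from_row(row, i) for i, row in df.iterrows())
    out = StudySet(records)
    if variant is not None:
        out = out.filter(variant=variant)
    return out


def write_studies(studies: StudySet, path: str | Path) -> None:
    """Write a study set back to the CSV schema (round-trips with read_studies)."""
    studies.to_frame().to_csv(path, index=False)


def validate_study(record: StudyRecord) -> list[str]:
    """Consistency findings for one record (empty list = clean).

    Checks genotype counts against any declared per-arm totals and the
    variant/stratum vocabularies. Findings are strings naming the record and
    the discrepancy; validation never raises.
    """
    findings: list[str] = []
    sid = record.study_id
    for arm_name, arm in (("case", record.cases), ("control", record.controls)):
        for g, v in zip(("hom_effect", "het", "hom_other"), arm.as_tuple()):
            if v < 0:
                findings.append(f"{sid}: negative {arm_name} count {g}={v}")
    if record.declared_n_cases is not None and record.cases.total() != record.declared_n_cases:
        findings.append(
            f"{sid}: case genotype counts sum to {record.cases.total()}, "
            f"declared total {record.declared_n_cases}"
        )
    if record.declared_n_controls is not None and record.controls.total() != record.declared_n_controls:
        findings.append(
            f"{sid}: control genotype counts sum to {record.controls.total()}, "
            f"declared total {record.declared_n_controls}"
        )
    if record.variant not in EFFECT_ALLELES:
        findings.append(f"{sid}: unknown variant {record.variant!r}")
    if record.ethnicity not in ETHNICITIES:
        findings.append(f"{sid}: unknown ethnicity {record.ethnicity!r}")
    if record.phenotype not in PHENOTYPES:
        findings.append(f"{sid}: unknown phenotype {record.phenotype!r}")
    if record.control_source not in CONTROL_SOURCES:
        findings.append(f"{sid}: unknown control source {record.control_source!r}")
    if record.cases.total() == 0:
        findings.append(f"{sid}: empty case arm")
    if record.controls.total() == 0:
        findings.append(f"{sid}: empty control arm")
    return findings


def totals(studies: StudySet) -> tuple[int, int, int]:
    """(total cases, total controls, number of records)."""
    n_cases = sum(r.cases.total() for r in studies)
    n_controls = sum(r.controls.total() for r in studies)
    return n_cases, n_controls, len(studies)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("snpmeta").joinpath("data", name)))


def load_table1(variant: Optional[str] = None) -> StudySet:
    """Load the packaged CDKN2B-AS1 study-characteristics fixture."""
    return read_studies(_data_path(TABLE1_FIXTURE), variant=variant)


def load_table2_reference() -> pd.DataFrame:
    """Published pooled estimates (point, CI, p-values) keyed like our reports."""
    return pd.read_csv(_data_path(TABLE2_REFERENCE), dtype={"p_heter": str, "p": str})
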