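"""Cohort table handling and variant-retention filtering.

The packaged fixture encodes the twelve-patient RTK/MAPK cohort: one row per
(patient, variant) with cancer type, the molecularly targeted agent (MTA)
given, the treatment basis (an assayed variant, or an amplification for
patients 1, 9 and 11), the per-variant oncogenic-activity call, the survival
reference data (PFS in months; every patient progressed, so all events are
observed) and the reporter pathway each variant was assayed on.

Variant-call filtering applies the sequencing retention thresholds: a call is
kept iff its strand ratio exceeds 0.2 and, for SNVs, allele frequency > 4%
with coverage > 30x, or, for indels, allele frequency > 10% with coverage
> 100x.  All comparisons are strict, so boundary values are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Variant",
    "VariantCall",
    "PatientRecord",
    "CohortSchemaError",
    "BUILTIN_COHORT",
    "COHORT_COLUMNS",
    "VARIANT_CALL_COLUMNS",
    "load_cohort",
    "write_cohort",
    "filter_variants",
    "load_variant_calls",
    "data_path",
]

#: identifier of the packaged 12-patient fixture
BUILTIN_COHORT = "rtk-mapk-12"

COHORT_COLUMNS = [
    "patient_id",
    "cancer_type",
    "mta",
    "treatment_basis",
    "basis_alteration",
    "gene",
    "protein_change",
    "variant_class",
    "reporter_pathway",
    "active",
    "pfs_months",
    "event",
]

VARIANT_CALL_COLUMNS = [
    "gene",
    "protein_change",
    "variant_type",
    "allele_frequency",
    "strand_ratio",
    "coverage",
]

_TREATMENT_BASES = {"assayed_variant", "amplification"}
_VARIANT_CLASSES = {"VUS", "known"}
_VARIANT_TYPES = {"SNV", "indel"}


class CohortSchemaError(ValueError):
    """Raised when a cohort or variant-call table violates the schema."""


@dataclass(frozen=True)
class Variant:
    """One assayed variant of a patient (e.g. KIT D572G)."""

    gene: str
    protein_change: str
    variant_class: str  # "VUS" or "known"
    reporter_pathway: str  # translocation reporter: ERK2/STAT3/RelA/FOXO1
    active: bool | None = None  # oncogenic-activity call, None if untested

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.protein_change)

    @property
    def label(self) -> str:
        return f"{self.gene} {self.protein_change}"


@dataclass(frozen=True)
class VariantCall:
    """A raw sequencing variant call with the fields the retention filter uses."""

    gene: str
    protein_change: str
    variant_type: str  # "SNV" or "indel"
    allele_frequency: float
    strand_ratio: float
    coverage: int

    def __post_init__(self) -> None:
        if self.variant_type not in _VARIANT_TYPES:
            raise ValueError(
                f"unknown variant_type {self.variant_type!r}; expected one of {sorted(_VARIANT_TYPES)}"
            )
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele_frequency {self.allele_frequency} outside [0, 1]")
        if not 0.0 <= self.strand_ratio <= 1.0:
            raise ValueError(f"strand_ratio {self.strand_ratio} outside [0, 1]")
        if self.coverage < 0:
            raise ValueError(f"coverage {self.coverage} must be >= 0")


@dataclass
class PatientRecord:
    """One cohort patient: treatment context, assayed variants and PFS."""

    patient_id: int
    cancer_type: str
    mta: str
    treatment_basis: str  # "assayed_variant" or "amplification"
    variants: list[Variant]
    pfs_months: float
    event: bool = True
    basis_alteration: str = ""  # e.g. "ERBB2 amplification" when basis is an amplification

    def __post_init__(self) -> None:
        if self.pfs_months <= 0:
            raise ValueError(f"patient {self.patient_id}: pfs_months must be > 0")
        if not self.variants:
            raise ValueError(f"patient {self.patient_id}: at least one variant required")
        if self.treatment_basis not in _TREATMENT_BASES:
            raise ValueError(
                f"patient {self.patient_id}: treatment_basis {self.treatment_basis!r}"
            )

    @property
    def variant_combo(self) -> frozenset[tuple[str, str]]:
        """Key identifying the patient's full (co-transfected) variant set."""
        return frozenset(v.key for v in self.variants)


def data_path(name: str) -> Path:
    """Path to a packaged data file."""
    return Path(resources.files("factpipe").joinpath("data", name))


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise CohortSchemaError(f"row {row}, column {column!r}: cannot parse boolean {value!r}")


def _cohort_frame(source: str | Path) -> pd.DataFrame:
    if source == BUILTIN_COHORT:
        source = data_path("cohort_table.csv")
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing columns: {missing}")
    return frame


def load_cohort(source: str | Path = BUILTIN_COHORT) -> list[PatientRecord]:
    """Read a cohort table (packaged fixture id or CSV path) into patient records.

    The CSV has one row per (patient, variant); rows of a patient must agree on
    the patient-level fields.  Malformed cells raise :class:`CohortSchemaError`
    naming the offending row and column.
    """
    frame = _cohort_frame(source)
    records: dict[int, PatientRecord] = {}
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # 1-based CSV line number incl. header
        try:
            pid = int(row["patient_id"])
        except ValueError as exc:
            raise CohortSchemaError(f"row {rownum}, column 'patient_id': {exc}") from exc
        try:
            pfs = float(row["pfs_months"])
        except ValueError as exc:
            raise CohortSchemaError(f"row {rownum}, column 'pfs_months': {exc}") from exc
        variant = Variant(
            gene=row["gene"],
            protein_change=row["protein_change"],
            variant_class=row["variant_class"],
            reporter_pathway=row["reporter_pathway"],
            active=_parse_bool(row["active"], rownum, "active"),
        )
        if variant.variant_class not in _VARIANT_CLASSES:
            raise CohortSchemaError(
                f"row {rownum}, column 'variant_class': {row['variant_class']!r}"
            )
        if pid in records:
            rec = records[pid]
            if rec.cancer_type != row["cancer_type"] or rec.mta != row["mta"]:
                raise CohortSchemaError(
                    f"row {rownum}, column 'patient_id': inconsistent patient-level fields"
                )
            rec.variants.append(variant)
        else:
            try:
                records[pid] = PatientRecord(
                    patient_id=pid,
                    cancer_type=row["cancer_type"],
                    mta=row["mta"],
                    treatment_basis=row["treatment_basis"],
                    basis_alteration=row["basis_alteration"],
                    variants=[variant],
                    pfs_months=pfs,
                    event=_parse_bool(row["event"], rownum, "event"),
                )
            except ValueError as exc:
                raise CohortSchemaError(f"row {rownum}: {exc}") from exc
    return [records[pid] for pid in sorted(records)]


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write patient records back to the one-row-per-variant CSV layout."""
    rows = []
    for rec in records:
        for v in rec.variants:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "cancer_type": rec.cancer_type,
                    "mta": rec.mta,
                    "treatment_basis": rec.treatment_basis,
                    "basis_alteration": rec.basis_alteration,
                    "gene": v.gene,
                    "protein_change": v.protein_change,
                    "variant_class": v.variant_class,
                    "reporter_pathway": v.reporter_pathway,
                    "active": v.active,
                    "pfs_months": rec.pfs_months,
                    "event": rec.event,
                }
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def filter_variants(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Apply the variant-retention thresholds, preserving input order.

    Retained iff strand_ratio > 0.2 and (SNV: allele_frequency > 0.04 and
    coverage > 30) or (indel: allele_frequency > 0.10 and coverage > 100).
    """
    kept = []
    for call in calls:
        if call.strand_ratio <= 0.2:
            continue
        if call.variant_type == "SNV":
            if call.allele_frequency > 0.04 and call.coverage > 30:
                kept.append(call)
        elif call.variant_type == "indel":
            if call.allele_frequency > 0.10 and call.coverage > 100:
                kept.append(call)
        else:  # pragma: no cover - blocked by VariantCall validation
            raise ValueError(f"unknown variant_type {call.variant_type!r}")
    return kept


def load_variant_calls(path: str | Path) -> list[VariantCall]:
    """Read a variant-call CSV (gene, protein_change, variant_type, allele_frequency, strand_ratio, coverage)."""
    frame = pd.read_csv(path)
    missing = [c for c in VARIANT_CALL_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"variant-call table missing columns: {missing}")
    calls = []
    for i, row in frame.iterrows():
        try:
            calls.append(
                VariantCall(
                    gene=str(row["gene"]),
                    protein_change=str(row["protein_change"]),
                    variant_type=str(row["variant_type"]),
                    allele_frequency=float(row["allele_frequency"]),
                    strand_ratio=float(row["strand_ratio"]),
                    coverage=int(row["coverage"]),
                )
            )
        except ValueError as exc:
            raise CohortSchemaError(f"row {int(i) + 2}: {exc}") from exc
    return calls
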