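"""Clinical patient-metadata parsing and cohort summaries.

The patient cohort ships with the package as a plain-CSV transcription
of the published patient-characteristics table of the saliva study (31
ER+ breast-cancer patients: ages at collection / diagnosis / death,
IDC/ILC histology, HER2 status, free-text metastasis sites and
treatment).  This module parses such tables, classifies metastatic
status, and computes cohort summaries (age mean +/- SD, percent
metastatic, treatment sub-group sizes by case-insensitive substring
match on the free-text treatment field).
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical CSV header for metadata tables.
METADATA_COLUMNS = (
    "patient_id",
    "age_collection",
    "age_diagnosis",
    "age_death",
    "idc",
    "ilc",
    "her2",
    "metastasis_sites",
    "treatment",
)

#: Canonical treatment labels counted by :func:`summarize_cohort`.
#: Matching is case-insensitive substring on the free-text treatment
#: field; "her2" matches e.g. "Targeted therapy for HER2".
DEFAULT_TREATMENT_LABELS = (
    "avastin",
    "palbocyclib",
    "hormonal",
    "chemotherapy",
    "her2",
    "afinitor",
)

_TRUE_TOKENS = {"√", "v", "true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"×", "x", "false", "f", "0", "no", "n", ""}
_HER2_POS = {"+", "pos", "positive"}
_HER2_NEG = {"-", "−", "–", "neg", "negative"}


class MetadataParseError(ValueError):
    """A metadata row or header could not be interpreted."""


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical metadata table."""

    patient_id: str
    age_collection: float | None
    age_diagnosis: float | None
    age_death: float | None
    idc: bool
    ilc: bool
    her2: str | None  # "+" or "-" when recorded
    metastasis_sites: str
    treatment: str

    def __post_init__(self) -> None:
        if (
            self.age_collection is not None
            and self.age_diagnosis is not None
            and self.age_diagnosis > self.age_collection
        ):
            raise ValueError(
                f"patient {self.patient_id}: age at diagnosis "
                f"({self.age_diagnosis}) exceeds age at collection "
                f"({self.age_collection})"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level summary of a metadata table."""

    n: int
    age_mean: float | None
    age_sd: float | None
    pct_metastatic: float
    treatment_counts: Mapping[str, int]


def _parse_flag(token: str, line: int, column: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise MetadataParseError(f"line {line}: unrecognised {column} flag {token!r}")


def _parse_her2(token: str, line: int) -> str | None:
    t = token.strip().lower()
    if t == "":
        return None
    if t in _HER2_POS:
        return "+"
    if t in _HER2_NEG:
        return "-"
    raise MetadataParseError(f"line {line}: unrecognised her2 status {token!r}")


def _parse_age(token: str, line: int, column: str) -> float | None:
    t = token.strip()
    if t == "":
        return None
    try:
        value = float(t)
    except ValueError as exc:
        raise MetadataParseError(f"line {line}: bad {column} value {token!r}") from exc
    if value <= 0:
        raise MetadataParseError(f"line {line}: {column} must be positive, got {value}")
    return value


def parse_metadata(source) -> list[PatientRecord]:
    """Parse a metadata CSV (path or text file-like) into records.

    Blank cells become absent values; check-mark / cross and plus /
    minus symbols are normalised to booleans and "+"/"-".  Malformed
    rows raise :class:`MetadataParseError` with the file line number.
    """
    if hasattr(source, "read"):
        return _parse_metadata_stream(source)
    with open(source, newline="", encoding="utf-8") as handle:
        return _parse_metadata_stream(handle)


def _parse_metadata_stream(handle) -> list[PatientRecord]:
    reader = csv.reader(handle)
    try:
        header = next(reader)
    except StopIteration:
        return []
    if tuple(h.strip() for h in header) != METADATA_COLUMNS:
        raise MetadataParseError(
            f"unexpected header {header!r}; expected {list(METADATA_COLUMNS)}"
        )
    records: list[PatientRecord] = []
    for line, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(METADATA_COLUMNS):
            raise MetadataParseError(
                f"line {line}: expected {len(METADATA_COLUMNS)} fields, got {len(row)}"
            )
        cells = dict(zip(METADATA_COLUMNS, row))
        try:
            record = PatientRecord(
                patient_id=cells["patient_id"].strip(),
                age_collection=_parse_age(cells["age_collection"], line, "age_collection"),
                age_diagnosis=_parse_age(cells["age_diagnosis"], line, "age_diagnosis"),
                age_death=_parse_age(cells["age_death"], line, "age_death"),
                idc=_parse_flag(cells["idc"], line, "idc"),
                ilc=_parse_flag(cells["ilc"], line, "ilc"),
                her2=_parse_her2(cells["her2"], line),
                metastasis_sites=cells["metastasis_sites"].strip(),
                treatment=cells["treatment"].strip(),
            )
        except ValueError as exc:
            if isinstance(exc, MetadataParseError):
                raise
            raise MetadataParseError(f"line {line}: {exc}") from exc
        records.append(record)
    return records


def _format_age(age: float | None) -> str:
    if age is None:
        return ""
    return str(int(age)) if float(age).is_integer() else repr(age)


def write_metadata(records: Iterable[PatientRecord], path) -> None:
    """Write records to CSV in the canonical schema (parse round-trips)."""

    def _write(handle) -> None:
        writer = csv.writer(handle)
        writer.writerow(METADATA_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    _format_age(r.age_collection),
                    _format_age(r.age_diagnosis),
                    _format_age(r.age_death),
                    "√" if r.idc else "×",
                    "√" if r.ilc else "×",
                    r.her2 or "",
                    r.metastasis_sites,
                    r.treatment,
                ]
            )

    if hasattr(path, "write"):
        _write(path)
    else:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            _write(handle)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Records as a DataFrame (for joins with expression profiles)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age_collection": [r.age_collection for r in records],
            "age_diagnosis": [r.age_diagnosis for r in records],
            "age_death": [r.age_death for r in records],
            "idc": [r.idc for r in records],
            "ilc": [r.ilc for r in records],
            "her2": [r.her2 for r in records],
            "metastasis_sites": [r.metastasis_sites for r in records],
            "treatment": [r.treatment for r in records],
        }
    )


def classify_metastatic(record: PatientRecord) -> bool:
    """Metastatic iff the site field is non-blank and not "Local disease".

    Blank cells count as non-metastatic: the source table does not
    distinguish "no data" from "no metastasis".
    """
    sites = record.metastasis_sites.strip().lower()
    return sites not in {"", "local disease"}


def count_treatment(records: Sequence[PatientRecord], label: str) -> int:
    """Number of records whose treatment text contains ``label`` (case-insensitive)."""
    needle = label.strip().lower()
    if not needle:
        raise ValueError("treatment label must be non-empty")
    return sum(needle in r.treatment.lower() for r in records)


def summarize_cohort(
    records: Sequence[PatientRecord],
    treatment_labels: Sequence[str] = DEFAULT_TREATMENT_LABELS,
) -> CohortSummary:
    """Summarise a cohort: age mean/SD, percent metastatic, treatment counts.

    Age statistics use age at collection with the sample (n-1) SD;
    records with a missing age are excluded from the age statistics with
    a log entry.  ``pct_metastatic`` is on the 0-100 scale.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarise an empty cohort")
    ages = [r.age_collection for r in records if r.age_collection is not None]
    n_missing = len(records) - len(ages)
    if n_missing:
        logger.info("excluding %d record(s) with missing collection age", n_missing)
    age_mean = float(np.mean(ages)) if ages else None
    age_sd = float(np.std(ages, ddof=1)) if len(ages) >= 2 else None
    pct = 100.0 * sum(classify_metastatic(r) for r in records) / len(records)
    counts = {label: count_treatment(records, label) for label in treatment_labels}
    return CohortSummary(
        n=len(records),
        age_mean=age_mean,
        age_sd=age_sd,
        pct_metastatic=pct,
        treatment_counts=counts,
    )


def load_patient_table() -> list[PatientRecord]:
    """Load the bundled 31-patient ER+ breast-cancer clinical table."""
    text = (
        resources.files("sfpanel")
        .joinpath("data/patient_characteristics.csv")
        .read_text(encoding="utf-8")
    )
    return parse_metadata(io.StringIO(text))
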