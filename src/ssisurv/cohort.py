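"""Cohort domain model and tabular I/O.

A surveillance cohort is a set of index colorectal surgeries together with
the structured events (admissions, reoperations, radiology orders,
antibiotic administrations) and free-text clinical notes recorded around
them, plus an optional reference-standard deep-SSI label per surgery.
Every downstream stage — the structured rule algorithm, the notes NLP,
the classifiers and the evaluation — consumes the :class:`CohortTable`
built here.

All date arithmetic downstream is whole-day differences from
``surgery_date`` (the surgery day is day 0).  Tables are read and written
as delimited text (CSV/TSV, header row required) or JSON lines; UTF-8
throughout, so Swedish characters survive a round trip.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

AUTHOR_ROLES = ("physician", "resident", "surgery_assistant", "nurse", "other")
#: The roles whose notes are under surveillance.
SURVEILLED_ROLES = ("physician", "resident", "surgery_assistant", "nurse")
MODALITIES = ("CT", "MRI", "X-ray", "ultrasound", "other")


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A table is missing a required column or a field fails to parse."""


class LinkageError(CohortError):
    """Identifiers do not resolve: duplicates or dangling references."""


@dataclass(frozen=True)
class SurgeryRecord:
    """One index colorectal surgery; its date is day 0 of follow-up."""

    surgery_id: str
    patient_id: str
    surgery_date: dt.date
    specialty: str
    department: str
    is_index: bool = True


@dataclass(frozen=True)
class AdmissionEvent:
    patient_id: str
    admit_date: dt.date
    discharge_date: Optional[dt.date]  # absent = still admitted
    department: str
    died_in_hospital: bool = False

    def __post_init__(self) -> None:
        if self.discharge_date is not None and self.discharge_date < self.admit_date:
            raise SchemaError(
                f"admission for {self.patient_id}: discharge "
                f"{self.discharge_date} precedes admission {self.admit_date}"
            )


@dataclass(frozen=True)
class ReoperationEvent:
    patient_id: str
    operation_date: dt.date
    specialty: str


@dataclass(frozen=True)
class RadiologyOrder:
    patient_id: str
    order_date: dt.date
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise SchemaError(
                f"unknown radiology modality {self.modality!r}; "
                f"expected one of {MODALITIES}"
            )


@dataclass(frozen=True)
class MedicationEvent:
    patient_id: str
    administration_date: dt.date
    atc_code: str

    def __post_init__(self) -> None:
        if not self.atc_code or self.atc_code != self.atc_code.upper():
            raise SchemaError(
                f"ATC code must be non-empty uppercase, got {self.atc_code!r}"
            )


@dataclass(frozen=True)
class ClinicalNote:
    """Free-text note linked to a surgery, with author role and date."""

    note_id: str
    patient_id: str
    surgery_id: str
    note_date: dt.date
    author_role: str
    text: str

    def __post_init__(self) -> None:
        if self.author_role not in AUTHOR_ROLES:
            raise SchemaError(
                f"unknown author role {self.author_role!r}; "
                f"expected one of {AUTHOR_ROLES}"
            )


@dataclass(frozen=True)
class ReferenceLabel:
    """Manually annotated deep-SSI outcome within 30 days of surgery."""

    surgery_id: str
    deep_ssi: bool
    ssi_onset_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ssi_onset_day is not None and not 0 <= self.ssi_onset_day <= 30:
            raise SchemaError(
                f"ssi_onset_day must lie in [0, 30], got {self.ssi_onset_day}"
            )


@dataclass
class CohortTable:
    """All tables of one cohort, validated and cross-linked."""

    surgeries: list[SurgeryRecord]
    admissions: list[AdmissionEvent] = field(default_factory=list)
    reoperations: list[ReoperationEvent] = field(default_factory=list)
    radiology: list[RadiologyOrder] = field(default_factory=list)
    medications: list[MedicationEvent] = field(default_factory=list)
    notes: list[ClinicalNote] = field(default_factory=list)
    labels: Optional[list[ReferenceLabel]] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        ids = [s.surgery_id for s in self.surgeries]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise LinkageError(f"duplicate surgery_id(s): {dupes}")
        known_surgeries = set(ids)
        known_patients = {s.patient_id for s in self.surgeries}
        dangling = sorted(
            {n.surgery_id for n in self.notes if n.surgery_id not in known_surgeries}
        )
        if self.labels is not None:
            dangling += sorted(
                {l.surgery_id for l in self.labels if l.surgery_id not in known_surgeries}
            )
        if dangling:
            raise LinkageError(f"unresolvable surgery_id reference(s): {dangling}")
        orphans = sorted(
            {
                e.patient_id
                for tab in (self.admissions, self.reoperations, self.radiology, self.medications)
                for e in tab
                if e.patient_id not in known_patients
            }
        )
        if orphans:
            raise LinkageError(f"event patient_id(s) with no surgery: {orphans}")

    # -- lookups ------------------------------------------------------
    def surgery(self, surgery_id: str) -> SurgeryRecord:
        for s in self.surgeries:
            if s.surgery_id == surgery_id:
                return s
        raise KeyError(surgery_id)

    def events_for(self, patient_id: str):
        """(admissions, reoperations, radiology, medications) of one patient."""
        return (
            [a for a in self.admissions if a.patient_id == patient_id],
            [r for r in self.reoperations if r.patient_id == patient_id],
            [r for r in self.radiology if r.patient_id == patient_id],
            [m for m in self.medications if m.patient_id == patient_id],
        )

    def notes_for(self, surgery_id: str) -> list[ClinicalNote]:
        return [n for n in self.notes if n.surgery_id == surgery_id]

    def labels_by_surgery(self) -> dict[str, ReferenceLabel]:
        if self.labels is None:
            raise CohortError("cohort carries no reference labels")
        return {l.surgery_id: l for l in self.labels}


# ---------------------------------------------------------------------
# Serialization: one file per table, field order fixed per record type.
# ---------------------------------------------------------------------

_TABLES: dict[str, type] = {
    "surgeries": SurgeryRecord,
    "admissions": AdmissionEvent,
    "reoperations": ReoperationEvent,
    "radiology": RadiologyOrder,
    "medications": MedicationEvent,
    "notes": ClinicalNote,
    "labels": ReferenceLabel,
}


def _to_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _from_cell(raw, typ, name: str, table: str):
    if raw is None or raw == "":
        if typ in (Optional[dt.date], Optional[int]):
            return None
        if typ is str:
            return ""
        raise SchemaError(f"{table}: empty value for required column {name!r}")
    if isinstance(raw, str):
        raw = raw.strip()
    try:
        if typ in (dt.date, Optional[dt.date]):
            return dt.date.fromisoformat(str(raw))
        if typ is bool:
            if isinstance(raw, bool):
                return raw
            return {"true": True, "false": False}[str(raw).lower()]
        if typ in (int, Optional[int]):
            return int(raw)
        return str(raw)
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"{table}: cannot parse column {name!r} value {raw!r}") from exc


def _record_to_row(rec) -> dict[str, str]:
    return {f.name: _to_cell(getattr(rec, f.name)) for f in dc_fields(rec)}


# Resolve annotations once (dataclass field.type is a string under
# `from __future__ import annotations`).
import typing as _typing

_FIELD_TYPES = {
    cls: _typing.get_type_hints(cls) for cls in _TABLES.values()
}


def write_cohort(cohort: CohortTable, directory, fmt: str = "csv", delimiter: str = ",") -> dict[str, Path]:
    """Write one file per table under *directory*; returns table → path.

    ``fmt`` is ``"csv"`` (delimited text with header) or ``"jsonl"``.
    The labels file is omitted when the cohort has no labels.  The writer
    and :func:`load_cohort` are exact inverses on every field.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {fmt!r}")
    ext = "csv" if fmt == "csv" else "jsonl"
    paths: dict[str, Path] = {}
    for table, cls in _TABLES.items():
        records = getattr(cohort, table)
        if table == "labels" and records is None:
            continue
        path = directory / f"{table}.{ext}"
        names = [f.name for f in dc_fields(cls)]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            if fmt == "csv":
                writer = csv.DictWriter(fh, fieldnames=names, delimiter=delimiter)
                writer.writeheader()
                for rec in records:
                    writer.writerow(_record_to_row(rec))
            else:
                for rec in records:
                    row = {f.name: getattr(rec, f.name) for f in dc_fields(cls)}
                    row = {
                        k: (v.isoformat() if isinstance(v, dt.date) else v)
                        for k, v in row.items()
                    }
                    fh.write(json.dumps(row, ensure_ascii=False) + "\n")
        paths[table] = path
    return paths


def _read_table(path: Path, cls, table: str, delimiter: str,
                columns: Optional[Mapping[str, str]] = None) -> list:
    def remap(row):
        if not columns:
            return row
        renamed = dict(row)
        for field_name, file_col in columns.items():
            if file_col in renamed:
                renamed[field_name] = renamed.pop(file_col)
        return renamed

    records = []
    if path.suffix == ".jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(
                        _row_to_record_typed(remap(json.loads(line)), cls, table)
                    )
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter=delimiter)
            if reader.fieldnames is None:
                return []
            for row in reader:
                records.append(_row_to_record_typed(remap(row), cls, table))
    return records


def _row_to_record_typed(row: Mapping, cls, table: str):
    types = _FIELD_TYPES[cls]
    kwargs = {}
    for f in dc_fields(cls):
        if f.name not in row:
            raise SchemaError(f"table {table!r}: missing required column {f.name!r}")
        kwargs[f.name] = _from_cell(row[f.name], types[f.name], f.name, table)
    return cls(**kwargs)


def load_cohort(paths_or_config, delimiter: str = ",") -> CohortTable:
    """Load a cohort from a directory, a table→path mapping, or a config file.

    Accepted forms:

    * a directory containing ``surgeries.csv`` … (or ``.tsv``/``.jsonl``);
    * a mapping ``{"surgeries": path, ...}``;
    * a YAML/JSON config file with a ``tables:`` mapping and optional
      ``delimiter:``.  A table entry may be a bare path or a mapping
      ``{path: ..., columns: {field: file_column, ...}}`` renaming file
      columns onto the canonical field names.

    Raises :class:`SchemaError` for missing columns or unparsable fields
    and :class:`LinkageError` for identifier problems; never returns a
    partially loaded cohort.
    """
    table_columns: dict[str, Mapping[str, str]] = {}
    if isinstance(paths_or_config, Mapping):
        table_paths = {k: Path(v) for k, v in paths_or_config.items()}
    else:
        p = Path(paths_or_config)
        if p.is_dir():
            table_paths = {}
            for table in _TABLES:
                for ext in ("csv", "tsv", "jsonl"):
                    cand = p / f"{table}.{ext}"
                    if cand.exists():
                        table_paths[table] = cand
                        break
        elif p.suffix in (".yaml", ".yml", ".json"):
            with open(p, encoding="utf-8") as fh:
                cfg = yaml.safe_load(fh)
            delimiter = cfg.get("delimiter", delimiter)
            base = p.parent
            table_paths = {}
            for k, v in cfg["tables"].items():
                if isinstance(v, Mapping):
                    table_paths[k] = base / v["path"]
                    table_columns[k] = v.get("columns", {})
                else:
                    table_paths[k] = base / v
        else:
            raise CohortError(f"cannot interpret cohort location {p}")

    if "surgeries" not in table_paths:
        raise SchemaError("no surgeries table found")
    loaded: dict[str, list] = {}
    for table, cls in _TABLES.items():
        if table in table_paths:
            sep = "\t" if table_paths[table].suffix == ".tsv" else delimiter
            loaded[table] = _read_table(
                table_paths[table], cls, table, sep, table_columns.get(table)
            )
    labels = loaded.pop("labels", None)
    return CohortTable(labels=labels, **{k: loaded.get(k, []) for k in _TABLES if k != "labels"})
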