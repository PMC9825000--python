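"""Delimited-table I/O and run configuration.

File dialects
-------------
events.csv    patient_id,event_date,code,code_type,code_system
patients.csv  patient_id,age,sex,diagnosis_date,observation_end,death_date,
              comorbidity_flags,reference_stage
codemap.csv   code_system,code,concept

Dates are ISO-8601 (YYYY-MM-DD).  The default delimiter is a comma; tab is
accepted via ``delimiter="\\t"`` or the ``delimiter`` config key.  Multiple
comorbidity flags are separated by ``;`` inside their field.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import RowParseError, SchemaError
from .records import CodedEvent, CodeMap, CodeType, Concept, PatientRecord
from .staging import parse_stage

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("patient_id", "event_date", "code", "code_type", "code_system")
PATIENT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "diagnosis_date",
    "observation_end",
    "death_date",
    "comorbidity_flags",
    "reference_stage",
)
CODEMAP_COLUMNS = ("code_system", "code", "concept")


def _parse_iso_date(text: str, line: int, column: str) -> date:
    try:
        return date.fromisoformat(text.strip())
    except ValueError as exc:
        raise RowParseError(line, f"bad {column} {text!r}: {exc}") from None


def _open_reader(path: str | Path, delimiter: str, required: Sequence[str]):
    path = Path(path)
    handle = path.open(newline="")
    reader = csv.DictReader(handle, delimiter=delimiter)
    for col in required:
        if reader.fieldnames is None or col not in reader.fieldnames:
            handle.close()
            raise SchemaError(col, str(path))
    return handle, reader


def read_event_table(path: str | Path, delimiter: str = ",") -> list[CodedEvent]:
    """Read an event table into CodedEvents sorted by (patient, date).

    Rows with unparseable dates or unknown code types raise RowParseError
    carrying the 1-based line number; nothing is silently dropped.
    """
    handle, reader = _open_reader(path, delimiter, EVENT_COLUMNS)
    events: list[CodedEvent] = []
    try:
        for i, row in enumerate(reader, start=2):  # line 1 is the header
            when = _parse_iso_date(row["event_date"], i, "event_date")
            try:
                ctype = CodeType(row["code_type"].strip().lower())
            except ValueError:
                raise RowParseError(
                    i, f"unknown code_type {row['code_type']!r}"
                ) from None
            code = row["code"].strip()
            if not code:
                raise RowParseError(i, "empty code")
            events.append(
                CodedEvent(
                    patient_id=row["patient_id"].strip(),
                    event_date=when,
                    code=code,
                    code_type=ctype,
                    code_system=row["code_system"].strip(),
                )
            )
    finally:
        handle.close()
    events.sort(key=lambda e: (e.patient_id, e.event_date, e.code))
    return events


def write_event_table(
    events: Iterable[CodedEvent], path: str | Path, delimiter: str = ","
) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [e.patient_id, e.event_date.isoformat(), e.code, e.code_type.value, e.code_system]
            )


def read_code_map(path: str | Path, delimiter: str = ",") -> CodeMap:
    """Read a code map; duplicate codes with conflicting concepts are an error."""
    handle, reader = _open_reader(path, delimiter, CODEMAP_COLUMNS)
    cmap = CodeMap()
    try:
        for i, row in enumerate(reader, start=2):
            try:
                concept = Concept(row["concept"].strip().lower())
            except ValueError:
                raise RowParseError(i, f"unknown concept {row['concept']!r}") from None
            cmap.add(row["code_system"].strip(), row["code"].strip(), concept)
    finally:
        handle.close()
    return cmap


def write_code_map(cmap: CodeMap, path: str | Path, delimiter: str = ",") -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(CODEMAP_COLUMNS)
        for (system, code), concept in sorted(cmap.items()):
            writer.writerow([system, code, concept.value])


def read_patient_table(
    path: str | Path,
    events: Sequence[CodedEvent] = (),
    delimiter: str = ",",
) -> list[PatientRecord]:
    """Read a patient table, attaching each patient's events from ``events``."""
    by_patient: dict[str, list[CodedEvent]] = {}
    for e in events:
        by_patient.setdefault(e.patient_id, []).append(e)

    handle, reader = _open_reader(path, delimiter, PATIENT_COLUMNS)
    records: list[PatientRecord] = []
    try:
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"].strip()
            death_raw = (row.get("death_date") or "").strip()
            flags_raw = (row.get("comorbidity_flags") or "").strip()
            stage_raw = (row.get("reference_stage") or "").strip()
            try:
                age = int(row["age"])
            except ValueError:
                raise RowParseError(i, f"bad age {row['age']!r}") from None
            records.append(
                PatientRecord(
                    patient_id=pid,
                    age_at_diagnosis=age,
                    sex=row["sex"].strip(),
                    diagnosis_date=_parse_iso_date(row["diagnosis_date"], i, "diagnosis_date"),
                    observation_end=_parse_iso_date(row["observation_end"], i, "observation_end"),
                    death_date=_parse_iso_date(death_raw, i, "death_date") if death_raw else None,
                    comorbidity_flags=frozenset(
                        f for f in flags_raw.split(";") if f
                    ),
                    reference_stage=parse_stage(stage_raw) if stage_raw else None,
                    events=by_patient.get(pid, []),
                )
            )
    finally:
        handle.close()
    return records


def write_patient_table(
    records: Iterable[PatientRecord], path: str | Path, delimiter: str = ","
) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(PATIENT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.age_at_diagnosis,
                    r.sex,
                    r.diagnosis_date.isoformat(),
                    r.observation_end.isoformat(),
                    r.death_date.isoformat() if r.death_date else "",
                    ";".join(sorted(r.comorbidity_flags)),
                    r.reference_stage.value if r.reference_stage else "",
                ]
            )


def write_report(
    results: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    delimiter: str = ",",
) -> list[Path]:
    """Write each named result table as ``<outdir>/<name>.csv``.

    Output is byte-stable for fixed inputs: tables are written in sorted name
    order with a fixed float format.  Empty tables are written with headers
    and a warning is logged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(results):
        df = results[name]
        if df.empty:
            logger.warning("result table %r is empty", name)
        target = outdir / f"{name}.csv"
        df.to_csv(target, sep=delimiter, index=False, float_format="%.6g")
        written.append(target)
    return written


@dataclass
class RunConfig:
    """Bundle of tunable settings loadable from a YAML/JSON key-value file.

    Unknown keys are rejected so that typos surface instead of silently
    falling back to defaults.
    """

    delimiter: str = ","
    seed: int = 0
    resolution: str = "coarse"
    bootstrap_resamples: int = 1000
    alpha: float = 0.05
    eligibility: dict = field(default_factory=dict)
    pattern: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
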