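"""Raw longitudinal coded data: events, patients, and the code map.

These containers mirror what an administrative claims extract or EHR export
provides: per-patient streams of dated diagnosis / procedure / medication
codes, plus a user-supplied map translating raw codes into the five treatment
concepts the classifier understands.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date

from .errors import CodeMapConflictError
from .staging import StageLabel


class CodeType(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"
    MEDICATION = "medication"


class Concept(str, enum.Enum):
    LUNG_CANCER_DX = "lung_cancer_dx"
    SURGERY = "surgery"
    CHEMO = "chemo"
    RADIOTHERAPY = "radiotherapy"
    OTHER = "other"


#: Concepts that count as cancer-directed treatment.
TREATMENT_CONCEPTS = frozenset(
    {Concept.SURGERY, Concept.CHEMO, Concept.RADIOTHERAPY}
)


@dataclass(frozen=True)
class CodedEvent:
    """One dated code for one patient."""

    patient_id: str
    event_date: date
    code: str
    code_type: CodeType
    code_system: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")
        if not isinstance(self.event_date, date):
            raise TypeError("event_date must be a datetime.date")


@dataclass
class PatientRecord:
    """A patient with demographics, observation window, and sorted events.

    ``external_diagnosis``, ``external_transfer`` and ``erroneous_stage`` are
    chart-review adjudication flags: they cannot be inferred from codes and
    are honored by cohort selection when set.
    """

    patient_id: str
    age_at_diagnosis: int
    sex: str
    diagnosis_date: date
    observation_end: date
    death_date: date | None = None
    comorbidity_flags: frozenset[str] = frozenset()
    reference_stage: StageLabel | None = None
    events: list[CodedEvent] = field(default_factory=list)
    external_diagnosis: bool = False
    external_transfer: bool = False
    erroneous_stage: bool = False

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.event_date)
        if self.death_date is not None and self.death_date > self.observation_end:
            raise ValueError("death_date must not exceed observation_end")

    @property
    def last_event_date(self) -> date | None:
        return self.events[-1].event_date if self.events else None


class CodeMap:
    """Total mapping (code_system, code) -> Concept; unmapped codes are OTHER."""

    def __init__(self, entries: dict[tuple[str, str], Concept] | None = None):
        self._entries: dict[tuple[str, str], Concept] = dict(entries or {})

    def add(self, code_system: str, code: str, concept: Concept) -> None:
        key = (code_system, code)
        existing = self._entries.get(key)
        if existing is not None and existing != concept:
            raise CodeMapConflictError(
                f"code {code!r} in system {code_system!r} mapped to both "
                f"{existing.value} and {concept.value}"
            )
        self._entries[key] = concept

    def lookup(self, code_system: str, code: str) -> Concept:
        return self._entries.get((code_system, code), Concept.OTHER)

    def concept_of(self, event: CodedEvent) -> Concept:
        return self.lookup(event.code_system, event.code)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()
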