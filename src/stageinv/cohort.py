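"""Cohort eligibility and exclusion filters with a per-criterion attrition log.

The validation-study design restricts to adults aged 20–75, free of prior
non-pulmonary cancer and cardiopulmonary comorbidity, whose last visit is
more than a minimum follow-up window before the end of observation, who
received cancer-directed treatment, and (when evaluating against a reference
standard) whose reference stage is available.  The application-study design
additionally requires a disease-free washout window before study entry.

Criteria are applied in a fixed order so attrition counts are reproducible:
record flags (chart-review exclusions) → age → comorbidity → washout →
follow-up → treatment presence → reference stage.  The order affects
per-step counts only, never the final cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Sequence

import pandas as pd

from .records import CodeMap, Concept, PatientRecord, TREATMENT_CONCEPTS


@dataclass
class EligibilityCriteria:
    age_min: int = 20
    age_max: int = 75
    min_followup_days: int = 180
    washout_days: int = 730
    exclude_comorbidity: bool = True
    require_reference_stage: bool = False
    require_treatment: bool = True
    apply_record_flags: bool = True

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.min_followup_days < 0 or self.washout_days < 0:
            raise ValueError("day windows must be non-negative")


@dataclass
class AttritionLog:
    """Ordered (criterion, excluded, remaining) rows; tabular Fig.-1 analogue."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, criterion: str, excluded: int, remaining: int) -> None:
        self.steps.append((criterion, excluded, remaining))

    @property
    def final_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["criterion", "excluded", "remaining"])


def passes_washout(
    record: PatientRecord,
    washout_days: int,
    code_map: CodeMap,
    study_start: date | None = None,
) -> bool:
    """True iff no lung-cancer diagnosis code falls inside the washout window.

    The window is half-open: events strictly between
    ``entry - washout_days`` (exclusive) and entry (exclusive) exclude the
    patient; an event exactly ``washout_days`` before entry does not, which
    mirrors a calendar-year washout (codes in 2002–2003 vs entry from 2004).
    """
    entry = record.diagnosis_date
    lower = entry - timedelta(days=washout_days)
    for event in record.events:
        if code_map.concept_of(event) is Concept.LUNG_CANCER_DX:
            if lower < event.event_date < entry:
                return False
    return True


def passes_followup(
    record: PatientRecord,
    min_followup_days: int,
    observation_end: date | None = None,
) -> bool:
    """True iff the last visit is *more than* ``min_followup_days`` before the
    end of observation (strict inequality)."""
    end = observation_end or record.observation_end
    last = record.last_event_date
    if last is None:
        return False
    return (end - last).days > min_followup_days


def _has_treatment(record: PatientRecord, code_map: CodeMap) -> bool:
    return any(code_map.concept_of(e) in TREATMENT_CONCEPTS for e in record.events)


def apply_criteria(
    records: Sequence[PatientRecord],
    criteria: EligibilityCriteria,
    code_map: CodeMap,
) -> tuple[list[PatientRecord], AttritionLog]:
    """Filter ``records`` by each criterion in the fixed order; log attrition.

    Conservation holds by construction: excluded counts across the log plus
    the final remaining count equal the input count.
    """
    steps: list[tuple[str, Callable[[PatientRecord], bool]]] = []
    if criteria.apply_record_flags:
        steps.append(
            (
                "record_flags",
                lambda r: not (
                    r.external_diagnosis or r.external_transfer or r.erroneous_stage
                ),
            )
        )
    steps.append(
        ("age", lambda r: criteria.age_min <= r.age_at_diagnosis <= criteria.age_max)
    )
    # comorbidity step always logged; excludes nothing in sensitivity mode
    steps.append(
        (
            "comorbidity",
            lambda r: (not criteria.exclude_comorbidity) or not r.comorbidity_flags,
        )
    )
    steps.append(
        (
            "washout",
            lambda r: passes_washout(r, criteria.washout_days, code_map),
        )
    )
    steps.append(
        ("followup", lambda r: passes_followup(r, criteria.min_followup_days))
    )
    if criteria.require_treatment:
        steps.append(("treatment_presence", lambda r: _has_treatment(r, code_map)))
    if criteria.require_reference_stage:
        steps.append(("reference_stage", lambda r: r.reference_stage is not None))

    log = AttritionLog()
    current = list(records)
    for name, keep in steps:
        kept = [r for r in current if keep(r)]
        log.record(name, len(current) - len(kept), len(kept))
        current = kept
    return current, log
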