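"""End-to-end conveniences wiring the modules together.

These are thin compositions used by the CLI and the test harness; every step
is an ordinary call into the underlying modules.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .classifier import (
    CLASS_TO_REFERENCE_STAGES,
    UNCLASSIFIED,
    classify_record,
)
from .metrics import ConfusionMatrix, confusion_matrix, metric_table, overall_accuracy
from .patterns import PatternConfig
from .records import CodeMap, PatientRecord
from .staging import StageLabel
from .survival import (
    ReferenceSurvivalTable,
    SurvivalCurve,
    SurvivalInput,
    km_estimate,
    compare_to_reference,
)


def classify_cohort(
    records: Sequence[PatientRecord],
    code_map: CodeMap,
    pattern_config: PatternConfig | None = None,
) -> pd.DataFrame:
    """Per-patient assignment table: class, rationale, fine and coarse stage."""
    rows = []
    for record in records:
        assignment, fine_stage = classify_record(
            record, code_map, pattern_config, resolution="fine"
        )
        coarse_stage = (
            classify_record(record, code_map, pattern_config, resolution="coarse")[1]
            if assignment.is_classified
            else None
        )
        rows.append(
            {
                "patient_id": record.patient_id,
                "class_id": assignment.class_id,
                "rationale": assignment.rationale,
                "inferred_stage_fine": fine_stage.value if fine_stage else "",
                "inferred_stage_coarse": coarse_stage.value if coarse_stage else "",
                "reference_stage": (
                    record.reference_stage.value if record.reference_stage else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def validation_pairs(
    records: Sequence[PatientRecord],
    code_map: CodeMap,
    pattern_config: PatternConfig | None = None,
) -> tuple[list[tuple[StageLabel, StageLabel]], int]:
    """(reference, inferred) coarse pairs plus the count excluded because the
    pattern was non-invertible or the reference stage missing."""
    pairs: list[tuple[StageLabel, StageLabel]] = []
    excluded = 0
    for record in records:
        assignment, inferred = classify_record(
            record, code_map, pattern_config, resolution="coarse"
        )
        if not assignment.is_classified or record.reference_stage is None:
            excluded += 1
            continue
        pairs.append((record.reference_stage.to_coarse(), inferred))
    return pairs, excluded


def evaluate_validation(
    records: Sequence[PatientRecord],
    code_map: CodeMap,
    pattern_config: PatternConfig | None = None,
    B: int = 1000,
    seed: int | None = None,
) -> dict:
    """Confusion matrix, overall accuracy, and the formatted metric table."""
    pairs, excluded = validation_pairs(records, code_map, pattern_config)
    cm: ConfusionMatrix = confusion_matrix(pairs)
    return {
        "pairs": pairs,
        "n_excluded_unclassified": excluded,
        "confusion_matrix": cm,
        "overall_accuracy": overall_accuracy(cm) if cm.n_total else None,
        "metric_table": metric_table(pairs, B=B, seed=seed) if pairs else pd.DataFrame(),
    }


def survival_by_class(
    records: Sequence[PatientRecord],
    code_map: CodeMap,
    pattern_config: PatternConfig | None = None,
) -> dict[int | str, list[SurvivalInput]]:
    """Group per-patient survival inputs by assigned class.

    Time origin is the diagnosis date; patients without a death date are
    censored at the end of observation.
    """
    groups: dict[int | str, list[SurvivalInput]] = {}
    for record in records:
        assignment, _ = classify_record(record, code_map, pattern_config)
        end = record.death_date or record.observation_end
        time_years = (end - record.diagnosis_date).days / 365.25
        groups.setdefault(assignment.class_id, []).append(
            SurvivalInput(time=max(time_years, 0.0), event=record.death_date is not None)
        )
    return groups


def reference_comparison(
    groups: Mapping[int | str, Sequence[SurvivalInput]],
    reference: ReferenceSurvivalTable | None = None,
) -> pd.DataFrame:
    """Per-class KM 2-/5-year survival against the reference stage rates."""
    reference = reference or ReferenceSurvivalTable.default()
    curves: dict[int, SurvivalCurve] = {
        cid: km_estimate(inputs)
        for cid, inputs in groups.items()
        if cid != UNCLASSIFIED and len(inputs) > 0
    }
    return compare_to_reference(curves, CLASS_TO_REFERENCE_STAGES, reference)
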