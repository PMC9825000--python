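"""The inverse of the treatment-decision rules.

Guideline-concordant therapy for NSCLC is a function of stage; restricted to
treatment patterns with a unique pre-image, that function can be inverted to
read the stage back off the observed treatment.  Seven invertible patterns
are recognized:

====  ==========================================  ===================
class  treatment pattern                           TNM 7th ed. stage
====  ==========================================  ===================
1     surgical resection only                      IA, IB, IIA
2     surgery + adjuvant chemo                     IIB
3     surgery + adjuvant chemo, then adjuvant RT   IIIA
4     surgery + adjuvant RT, then adjuvant chemo   IIIA
5     neoadjuvant chemo + surgery                  IIIA
6     concurrent chemoradiation, no surgery        IIIB
7     chemotherapy only                            IV
====  ==========================================  ===================

Class 2 in principle also covers some stage-IIA patients and class 6 some
stage-IIIA patients; those minority pre-images are deliberately ignored so
each class projects to a single stage.  Patterns outside the table (RT only,
trimodality chemoradiation before surgery, chemo in no recognizable temporal
relation to surgery, ...) are UNCLASSIFIED — a value, not an error.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .errors import ContractError
from .patterns import (
    AdjuvantOrder,
    ChemoRelation,
    PatternConfig,
    RTRelation,
    TreatmentPattern,
    build_courses,
    extract_pattern,
)
from .records import CodeMap, PatientRecord
from .staging import StageLabel, coarse, fine

UNCLASSIFIED = "unclassified"

CLASS_IDS = (1, 2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class ClassAssignment:
    class_id: int | str  # 1..7 or UNCLASSIFIED
    rationale: str

    @property
    def is_classified(self) -> bool:
        return self.class_id != UNCLASSIFIED


def _p(has_surgery, chemo, rt, order=None) -> Callable[[TreatmentPattern], bool]:
    def pred(pattern: TreatmentPattern) -> bool:
        return (
            pattern.has_surgery == has_surgery
            and pattern.chemo_relation is chemo
            and pattern.rt_relation is rt
            and (order is None or pattern.adjuvant_order is order)
        )

    return pred


#: One predicate per invertible row; mutually exclusive by construction
#: (distinct field combinations), asserted exhaustively in the test suite.
CLASS_PREDICATES: dict[int, Callable[[TreatmentPattern], bool]] = {
    1: _p(True, ChemoRelation.NONE, RTRelation.NONE),
    2: _p(True, ChemoRelation.ADJUVANT, RTRelation.NONE),
    3: _p(True, ChemoRelation.ADJUVANT, RTRelation.ADJUVANT, AdjuvantOrder.CHEMO_FIRST),
    4: _p(True, ChemoRelation.ADJUVANT, RTRelation.ADJUVANT, AdjuvantOrder.RT_FIRST),
    5: _p(True, ChemoRelation.NEOADJUVANT, RTRelation.NONE),
    6: _p(False, ChemoRelation.CONCURRENT_WITH_RT, RTRelation.CONCURRENT_WITH_CHEMO),
    7: _p(False, ChemoRelation.STANDALONE, RTRelation.NONE),
}

_CLASS_RATIONALE = {
    1: "surgical resection only",
    2: "surgery with adjuvant chemotherapy",
    3: "surgery with adjuvant chemotherapy then adjuvant radiotherapy",
    4: "surgery with adjuvant radiotherapy then adjuvant chemotherapy",
    5: "neoadjuvant chemotherapy then surgery",
    6: "concurrent chemoradiation without surgery",
    7: "chemotherapy only",
}

#: Stage projection per class.  Fine scale: class 1 covers IA/IB/IIA, kept as
#: the aggregate label; classes 3–5 all invert to IIIA.
CLASS_TO_FINE: dict[int, str] = {
    1: "I_IIA", 2: "IIB", 3: "IIIA", 4: "IIIA", 5: "IIIA", 6: "IIIB", 7: "IV",
}
CLASS_TO_COARSE: dict[int, str] = {
    1: "I", 2: "II", 3: "III", 4: "III", 5: "III", 6: "III", 7: "IV",
}

#: Reference-table stages each class corresponds to (survival comparison).
CLASS_TO_REFERENCE_STAGES: dict[int, tuple[str, ...]] = {
    1: ("IA", "IB", "IIA"),
    2: ("IIB",),
    3: ("IIIA",),
    4: ("IIIA",),
    5: ("IIIA",),
    6: ("IIIB",),
    7: ("IV",),
}


def classify_pattern(pattern: TreatmentPattern) -> ClassAssignment:
    """Match the pattern against the seven invertible rows."""
    for class_id, predicate in CLASS_PREDICATES.items():
        if predicate(pattern):
            return ClassAssignment(class_id, _CLASS_RATIONALE[class_id])
    return ClassAssignment(
        UNCLASSIFIED,
        "no invertible treatment-pattern row matches "
        f"(surgery={pattern.has_surgery}, chemo={pattern.chemo_relation.value}, "
        f"rt={pattern.rt_relation.value})",
    )


def class_to_stage(
    class_id: int, resolution: str = "coarse", class1_coarse: str = "I"
) -> StageLabel:
    """Project a class to its TNM stage at the requested resolution.

    ``class1_coarse`` settles which single coarse stage the surgery-only
    class maps to when a coarse label is forced; stage I is the default since
    it dominates that class's pre-image.
    """
    if class_id not in CLASS_TO_FINE:
        raise ContractError(f"class_id must be 1..7, got {class_id!r}")
    if resolution == "fine":
        return fine(CLASS_TO_FINE[class_id])
    if resolution == "coarse":
        if class_id == 1:
            if class1_coarse not in ("I", "II"):
                raise ValueError("class1_coarse must be 'I' or 'II'")
            return coarse(class1_coarse)
        return coarse(CLASS_TO_COARSE[class_id])
    raise ValueError(f"unknown resolution {resolution!r}")


def classify_record(
    record: PatientRecord,
    code_map: CodeMap,
    pattern_config: PatternConfig | None = None,
    resolution: str = "coarse",
) -> tuple[ClassAssignment, StageLabel | None]:
    """events → courses → pattern → class → stage; fully deterministic."""
    courses = build_courses(record.events, code_map, pattern_config)
    pattern = extract_pattern(courses, pattern_config)
    assignment = classify_pattern(pattern)
    stage = (
        class_to_stage(assignment.class_id, resolution)
        if assignment.is_classified
        else None
    )
    return assignment, stage
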