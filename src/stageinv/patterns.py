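"""Collapse coded events into treatment courses and extract the temporal
treatment pattern — the domain of the inverse decision rule.

A *course* is a maximal run of same-modality events whose inter-event gaps do
not exceed ``course_gap_days`` (default 30: one missed 3-weekly chemo cycle
still merges; a two-month gap starts a new course).  The *pattern* summarizes
how chemotherapy and radiotherapy relate in time to the first surgical
resection (neoadjuvant / adjuvant / concurrent / standalone); all temporal
windows are configurable because claims data never label intent explicitly.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

from .errors import ContractError
from .records import CodedEvent, CodeMap, Concept


class Modality(str, enum.Enum):
    SURGERY = "surgery"
    CHEMO = "chemo"
    RADIOTHERAPY = "radiotherapy"


_CONCEPT_TO_MODALITY = {
    Concept.SURGERY: Modality.SURGERY,
    Concept.CHEMO: Modality.CHEMO,
    Concept.RADIOTHERAPY: Modality.RADIOTHERAPY,
}


class ChemoRelation(str, enum.Enum):
    NONE = "none"
    NEOADJUVANT = "neoadjuvant"
    ADJUVANT = "adjuvant"
    CONCURRENT_WITH_RT = "concurrent_with_rt"
    STANDALONE = "standalone"


class RTRelation(str, enum.Enum):
    NONE = "none"
    ADJUVANT = "adjuvant"
    CONCURRENT_WITH_CHEMO = "concurrent_with_chemo"
    STANDALONE = "standalone"


class AdjuvantOrder(str, enum.Enum):
    CHEMO_FIRST = "chemo_first"
    RT_FIRST = "rt_first"


@dataclass(frozen=True)
class TreatmentCourse:
    modality: Modality
    start: date
    end: date
    n_events: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("course start must be <= end")
        if self.n_events < 1:
            raise ValueError("course must contain >= 1 event")
        if self.modality is Modality.SURGERY and self.start != self.end:
            raise ValueError("surgery courses are single-day")


@dataclass
class PatternConfig:
    course_gap_days: int = 30
    concurrency_overlap: bool = True
    concurrency_start_window_days: int = 30
    neoadjuvant_window_days: int = 120
    adjuvant_window_days: int = 180

    def __post_init__(self) -> None:
        for name in (
            "course_gap_days",
            "concurrency_start_window_days",
            "neoadjuvant_window_days",
            "adjuvant_window_days",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TreatmentPattern:
    has_surgery: bool
    chemo_relation: ChemoRelation
    rt_relation: RTRelation
    adjuvant_order: AdjuvantOrder | None = None
    raw_courses: list[TreatmentCourse] = field(default_factory=list)


def build_courses(
    events: Sequence[CodedEvent],
    code_map: CodeMap,
    config: PatternConfig | None = None,
) -> list[TreatmentCourse]:
    """Merge treatment-mapped events into modality courses.

    Duplicate events (same date, same modality) count once; surgery events
    never merge across days — each surgery date is its own single-day course,
    so the first resection date stays a clean anchor.
    """
    config = config or PatternConfig()
    # distinct (modality, date) pairs, per modality, sorted
    dates: dict[Modality, list[date]] = {m: [] for m in Modality}
    seen: set[tuple[Modality, date]] = set()
    for event in sorted(events, key=lambda e: e.event_date):
        modality = _CONCEPT_TO_MODALITY.get(code_map.concept_of(event))
        if modality is None:
            continue
        key = (modality, event.event_date)
        if key in seen:
            continue
        seen.add(key)
        dates[modality].append(event.event_date)

    courses: list[TreatmentCourse] = []
    for modality, ds in dates.items():
        if modality is Modality.SURGERY:
            courses.extend(
                TreatmentCourse(modality, d, d, 1) for d in ds
            )
            continue
        run: list[date] = []
        for d in ds:
            if run and (d - run[-1]).days > config.course_gap_days:
                courses.append(TreatmentCourse(modality, run[0], run[-1], len(run)))
                run = []
            run.append(d)
        if run:
            courses.append(TreatmentCourse(modality, run[0], run[-1], len(run)))
    courses.sort(key=lambda c: (c.start, c.modality.value))
    return courses


def is_concurrent(
    chemo: TreatmentCourse, rt: TreatmentCourse, config: PatternConfig | None = None
) -> bool:
    """Concurrency = calendar overlap of at least one day, or starts within
    ``concurrency_start_window_days`` of each other (CCRT coding dates jitter)."""
    config = config or PatternConfig()
    if chemo.modality is not Modality.CHEMO or rt.modality is not Modality.RADIOTHERAPY:
        raise ContractError("is_concurrent expects a chemo course and an RT course")
    overlap = config.concurrency_overlap and (
        chemo.start <= rt.end and rt.start <= chemo.end
    )
    near_start = (
        abs((chemo.start - rt.start).days) <= config.concurrency_start_window_days
    )
    return overlap or near_start


def _relations_to_surgery(
    course: TreatmentCourse, surgery: TreatmentCourse, config: PatternConfig
) -> str:
    """'neoadjuvant', 'adjuvant' or 'outside' for one course vs the anchor."""
    neo_lo = surgery.start - timedelta(days=config.neoadjuvant_window_days)
    adj_hi = surgery.start + timedelta(days=config.adjuvant_window_days)
    if course.end < surgery.start and course.start >= neo_lo:
        return "neoadjuvant"
    if course.start > surgery.start and course.start <= adj_hi:
        return "adjuvant"
    return "outside"


def extract_pattern(
    courses: Sequence[TreatmentCourse], config: PatternConfig | None = None
) -> TreatmentPattern:
    """Summarize the temporal relations of chemo and RT courses.

    The first surgery anchors all relations.  With surgery present,
    overlapping post-operative chemo+RT is recorded as adjuvant for both
    (concurrency is reserved for the non-surgical chemoradiation path).
    Conflicting relations across multiple courses of one modality (e.g. both
    neoadjuvant and adjuvant chemo) reduce to STANDALONE: no single invertible
    row fits, and the classifier reports them as such.
    """
    config = config or PatternConfig()
    courses = sorted(courses, key=lambda c: c.start)
    surgeries = [c for c in courses if c.modality is Modality.SURGERY]
    chemos = [c for c in courses if c.modality is Modality.CHEMO]
    rts = [c for c in courses if c.modality is Modality.RADIOTHERAPY]
    surgery = surgeries[0] if surgeries else None

    chemo_rel = ChemoRelation.NONE
    rt_rel = RTRelation.NONE
    order: AdjuvantOrder | None = None
    first_adj_chemo: date | None = None
    first_adj_rt: date | None = None

    if surgery is not None:
        if chemos:
            rels = {_relations_to_surgery(c, surgery, config) for c in chemos}
            if rels == {"neoadjuvant"}:
                chemo_rel = ChemoRelation.NEOADJUVANT
            elif rels == {"adjuvant"}:
                chemo_rel = ChemoRelation.ADJUVANT
                first_adj_chemo = min(
                    c.start for c in chemos
                    if _relations_to_surgery(c, surgery, config) == "adjuvant"
                )
            else:
                chemo_rel = ChemoRelation.STANDALONE
        if rts:
            rels = {_relations_to_surgery(c, surgery, config) for c in rts}
            if rels == {"adjuvant"}:
                rt_rel = RTRelation.ADJUVANT
                first_adj_rt = min(
                    c.start for c in rts
                    if _relations_to_surgery(c, surgery, config) == "adjuvant"
                )
            else:
                # neoadjuvant RT is not an invertible row; treat as standalone
                rt_rel = RTRelation.STANDALONE
    else:
        concurrent = any(
            is_concurrent(c, r, config) for c in chemos for r in rts
        )
        if chemos:
            chemo_rel = (
                ChemoRelation.CONCURRENT_WITH_RT if concurrent
                else ChemoRelation.STANDALONE
            )
        if rts:
            rt_rel = (
                RTRelation.CONCURRENT_WITH_CHEMO if concurrent
                else RTRelation.STANDALONE
            )

    if chemo_rel is ChemoRelation.ADJUVANT and rt_rel is RTRelation.ADJUVANT:
        assert first_adj_chemo is not None and first_adj_rt is not None
        order = (
            AdjuvantOrder.CHEMO_FIRST
            if first_adj_chemo <= first_adj_rt
            else AdjuvantOrder.RT_FIRST
        )

    return TreatmentPattern(
        has_surgery=surgery is not None,
        chemo_relation=chemo_rel,
        rt_relation=rt_rel,
        adjuvant_order=order,
        raw_courses=list(courses),
    )
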