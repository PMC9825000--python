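"""Synthetic NSCLC cohorts with known true stages, guideline-concordant coded
treatment sequences, and stage-calibrated survival.

The generator emulates the study conditions of the two real cohorts the
pipeline is designed for, without any restricted data:

* the validation cohort's coarse stage mixture (68.6 / 8.9 / 7.9 / 14.5 %
  for stages I / II / III / IV);
* treatment sequences generated *forward* from the guideline decision rules
  — the exact rules the classifier inverts — with a tunable concordance
  probability and two deviation modes;
* stage-specific Weibull survival calibrated so that S(2) and S(5) hit the
  published per-stage reference rates exactly (an exponential law has one
  parameter and cannot match both horizons);
* uniform accrual with administrative censoring.

Timings are stylized but clinically shaped: surgery two weeks after
diagnosis, 3-weekly chemotherapy cycles starting a month post-op, 30-day
radiotherapy courses, neoadjuvant chemotherapy ending three weeks before
resection, overlapping courses for concurrent chemoradiation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .io import write_code_map, write_event_table, write_patient_table
from .records import CodedEvent, CodeMap, CodeType, Concept, PatientRecord
from .staging import FINE_TO_COARSE, fine
from .survival import ReferenceSurvivalTable

#: Fine-stage mixture: coarse mix from the validation cohort, stage I split
#: IA:IB = 60:40, coarse II assigned to IIB (the classifier's invertible
#: subdomain folds IIA into the surgery-only class), coarse III split evenly.
DEFAULT_STAGE_DISTRIBUTION: dict[str, float] = {
    "IA": 0.686 * 0.6,
    "IB": 0.686 * 0.4,
    "IIB": 0.089,
    "IIIA": 0.079 * 0.5,
    "IIIB": 0.079 * 0.5,
    "IV": 0.145,
}

#: Stage IIIA inverts to three classes; default weights follow the observed
#: class sizes in the application cohort (1021 : 999 : 448).
DEFAULT_IIIA_CLASS_WEIGHTS: dict[int, float] = {3: 1021.0, 4: 999.0, 5: 448.0}

_STAGE_TO_CLASS: dict[str, int | None] = {
    "IA": 1, "IB": 1, "IIA": 1, "IIB": 2, "IIIA": None,  # drawn from weights
    "IIIB": 6, "IV": 7,
}

_DX = ("ICD10", "C34", CodeType.DIAGNOSIS)
_SURG = ("EDI", "SURG01", CodeType.PROCEDURE)
_CHEMO = ("EDI", "CHEMO01", CodeType.MEDICATION)
_RT = ("EDI", "RT01", CodeType.PROCEDURE)


def default_code_map() -> CodeMap:
    """Code map matching the generator's emitted codes."""
    cmap = CodeMap()
    cmap.add("ICD10", "C34", Concept.LUNG_CANCER_DX)
    cmap.add("EDI", "SURG01", Concept.SURGERY)
    cmap.add("EDI", "CHEMO01", Concept.CHEMO)
    cmap.add("EDI", "RT01", Concept.RADIOTHERAPY)
    return cmap


def calibrate_weibull(s2: float, s5: float) -> tuple[float, float]:
    """Weibull (shape k, scale λ in years) hitting S(2)=s2 and S(5)=s5.

    Closed form from S(t) = exp(−(t/λ)^k):
    k = ln(ln s5 / ln s2) / ln(5/2),  λ = 2 / (−ln s2)^(1/k).
    """
    if not (0.0 < s5 < s2 < 1.0):
        raise CalibrationError(
            f"need 0 < 5-year < 2-year < 1, got s2={s2}, s5={s5}"
        )
    k = math.log(math.log(s5) / math.log(s2)) / math.log(5 / 2)
    lam = 2.0 / (-math.log(s2)) ** (1.0 / k)
    return k, lam


def default_survival_params(
    reference: ReferenceSurvivalTable | None = None,
) -> dict[str, tuple[float, float]]:
    """Per fine stage (shape, scale), calibrated to the reference table."""
    reference = reference or ReferenceSurvivalTable.default()
    return {
        stage: calibrate_weibull(
            reference.survival(stage, 2), reference.survival(stage, 5)
        )
        for stage in reference.stages()
    }


@dataclass
class SimulationParams:
    n_patients: int = 1000
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DISTRIBUTION)
    )
    concordance: float = 1.0
    deviation_model: str = "random_other_class"  # or "unclassified"
    iiia_class_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_IIIA_CLASS_WEIGHTS)
    )
    survival_params: dict[str, tuple[float, float]] = field(
        default_factory=default_survival_params
    )
    study_start: date = date(2011, 1, 1)
    accrual_years: float = 5.0
    horizon_years: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.stage_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=5e-3):
            raise ValueError(f"stage_distribution sums to {total}, expected 1")
        # renormalize away printed-percentage rounding slack
        self.stage_distribution = {
            s: p / total for s, p in self.stage_distribution.items()
        }
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if self.deviation_model not in ("random_other_class", "unclassified"):
            raise ValueError(f"unknown deviation_model {self.deviation_model!r}")
        for stage, (k, lam) in self.survival_params.items():
            if k <= 0 or lam <= 0:
                raise ValueError(f"non-positive Weibull parameters for {stage}")


@dataclass
class SyntheticTruth:
    """Ground-truth table emitted alongside the records."""

    frame: pd.DataFrame  # patient_id, true_fine_stage, true_coarse_stage,
    #                      assigned_class, concordant, time_years, event


def _event(patient_id: str, day0: date, offset: int, spec) -> CodedEvent:
    system, code, ctype = spec
    return CodedEvent(
        patient_id=patient_id,
        event_date=day0 + timedelta(days=offset),
        code=code,
        code_type=ctype,
        code_system=system,
    )


def canonical_event_offsets(class_id: int) -> list[tuple[int, tuple]]:
    """Day offsets (from diagnosis) of the canonical sequence for a class."""
    chemo_cycles = lambda start, n: [(start + 21 * i, _CHEMO) for i in range(n)]
    rt_course = lambda start: [(start + 5 * i, _RT) for i in range(7)]  # 30 days
    if class_id == 1:
        return [(14, _SURG)]
    if class_id == 2:
        return [(14, _SURG)] + chemo_cycles(44, 4)
    if class_id == 3:
        return [(14, _SURG)] + chemo_cycles(44, 4) + rt_course(130)
    if class_id == 4:
        return [(14, _SURG)] + rt_course(44) + chemo_cycles(84, 4)
    if class_id == 5:
        return chemo_cycles(7, 4) + [(91, _SURG)]
    if class_id == 6:
        return chemo_cycles(14, 3) + rt_course(14)
    if class_id == 7:
        return chemo_cycles(14, 6)
    raise ValueError(f"class_id must be 1..7, got {class_id!r}")


def canonical_events(
    class_id: int | None, patient_id: str, diagnosis_date: date
) -> list[CodedEvent]:
    """Coded events for a class's canonical sequence (None → RT only,
    a deliberately non-invertible pattern), led by the diagnosis code."""
    offsets: list[tuple[int, tuple]] = [(0, _DX)]
    if class_id is None:
        offsets += [(14 + 5 * i, _RT) for i in range(7)]
    else:
        offsets += canonical_event_offsets(class_id)
    return sorted(
        (_event(patient_id, diagnosis_date, off, spec) for off, spec in offsets),
        key=lambda e: e.event_date,
    )


def _concordant_class(stage: str, params: SimulationParams, rng) -> int:
    cls = _STAGE_TO_CLASS[stage]
    if cls is not None:
        return cls
    ids = sorted(params.iiia_class_weights)
    w = np.array([params.iiia_class_weights[i] for i in ids], dtype=float)
    return int(rng.choice(ids, p=w / w.sum()))


def sample_treatment_sequence(
    true_stage: str,
    params: SimulationParams,
    rng: np.random.Generator,
    patient_id: str = "P0",
    diagnosis_date: date = date(2011, 1, 1),
) -> tuple[list[CodedEvent], int | None, bool]:
    """Events for one patient plus the emitted class and a concordance flag.

    With probability ``concordance`` the guideline class for the true stage
    is emitted; otherwise a uniformly drawn *other* class
    (``random_other_class``) or an RT-only non-invertible sequence
    (``unclassified``).
    """
    guideline = _concordant_class(true_stage, params, rng)
    concordant = bool(rng.random() < params.concordance)
    if concordant:
        emitted: int | None = guideline
    elif params.deviation_model == "random_other_class":
        others = [c for c in range(1, 8) if c != guideline]
        emitted = int(rng.choice(others))
    else:
        emitted = None
    return canonical_events(emitted, patient_id, diagnosis_date), emitted, concordant


def sample_survival(
    true_stage: str,
    params: SimulationParams,
    rng: np.random.Generator,
    entry_years: float | None = None,
) -> tuple[float, bool]:
    """(follow-up time in years, death observed) for one patient.

    Death time ~ Weibull(shape, scale) for the stage; administrative
    censoring at ``horizon_years − entry``, entry uniform over the accrual
    window when not supplied.
    """
    k, lam = params.survival_params[true_stage]
    if entry_years is None:
        entry_years = float(rng.uniform(0.0, params.accrual_years))
    censor = max(params.horizon_years - entry_years, 0.0)
    death = float(lam * rng.weibull(k))
    if death <= censor:
        return death, True
    return censor, False


def simulate_cohort(
    params: SimulationParams,
) -> tuple[list[PatientRecord], SyntheticTruth]:
    """Generate ``n_patients`` records with events, demographics inside the
    eligibility bounds, true reference stage, and survival fields.

    Each patient consumes an independent substream spawned from the single
    seed, so the cohort is reproducible and insensitive to generation order.
    """
    stages = sorted(params.stage_distribution)
    probs = np.array([params.stage_distribution[s] for s in stages])
    children = np.random.SeedSequence(params.seed).spawn(params.n_patients)

    records: list[PatientRecord] = []
    truth_rows = []
    observation_end = params.study_start + timedelta(
        days=round(params.horizon_years * 365.25)
    )
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"SYN{i:06d}"
        stage = str(rng.choice(stages, p=probs))
        entry_years = float(rng.uniform(0.0, params.accrual_years))
        diagnosis_date = params.study_start + timedelta(
            days=round(entry_years * 365.25)
        )
        events, emitted, concordant = sample_treatment_sequence(
            stage, params, rng, pid, diagnosis_date
        )
        time_years, death = sample_survival(stage, params, rng, entry_years)
        death_date = (
            # min() guards day-rounding pushing the date past observation_end
            min(
                diagnosis_date + timedelta(days=round(time_years * 365.25)),
                observation_end,
            )
            if death
            else None
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                age_at_diagnosis=int(rng.integers(30, 75)),
                sex="M" if rng.random() < 0.65 else "F",
                diagnosis_date=diagnosis_date,
                observation_end=observation_end,
                death_date=death_date,
                reference_stage=fine(stage),
                events=events,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_fine_stage": stage,
                "true_coarse_stage": FINE_TO_COARSE[stage],
                "assigned_class": emitted if emitted is not None else "unclassified",
                "concordant": concordant,
                "time_years": time_years,
                "event": death,
            }
        )
    return records, SyntheticTruth(pd.DataFrame(truth_rows))


def write_cohort(
    records: list[PatientRecord],
    truth: SyntheticTruth,
    outdir: str | Path,
    delimiter: str = ",",
) -> None:
    """Dump events.csv / patients.csv / codemap.csv / truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = [e for r in records for e in r.events]
    write_event_table(events, outdir / "events.csv", delimiter)
    write_patient_table(records, outdir / "patients.csv", delimiter)
    write_code_map(default_code_map(), outdir / "codemap.csv", delimiter)
    truth.frame.to_csv(outdir / "truth.csv", sep=delimiter, index=False)
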