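from datetime import date, timedelta

import pytest

from stageinv.records import CodedEvent, CodeType, PatientRecord
from stageinv.simulate import default_code_map


@pytest.fixture
def code_map():
    return default_code_map()


def make_event(pid: str, day: int, concept: str, origin: date = date(2011, 1, 1)) -> CodedEvent:
    """Event `day` days after origin, by treatment concept shorthand."""
    spec = {
        "dx": ("ICD10", "C34", CodeType.DIAGNOSIS),
        "surgery": ("EDI", "SURG01", CodeType.PROCEDURE),
        "chemo": ("EDI", "CHEMO01", CodeType.MEDICATION),
        "rt": ("EDI", "RT01", CodeType.PROCEDURE),
        "other": ("EDI", "MISC99", CodeType.PROCEDURE),
    }[concept]
    system, code, ctype = spec
    return CodedEvent(pid, origin + timedelta(days=day), code, ctype, system)


def make_record(pid="P1", age=60, events=(), reference_stage=None, **kw) -> PatientRecord:
    defaults = dict(
        patient_id=pid,
        age_at_diagnosis=age,
        sex="M",
        diagnosis_date=date(2011, 1, 1),
        observation_end=date(2020, 1, 1),
        events=list(events),
        reference_stage=reference_stage,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)
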