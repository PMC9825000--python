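"""TNM (7th edition) stage labels at coarse (I–IV) and fine (IA–IV) resolution.

The fine scale carries one extra value, ``I_IIA``: the treatment-based
classifier cannot separate stages IA, IB and IIA (all are treated by surgery
alone under the guideline), so survival reporting aggregates them into a
single label.
"""
from __future__ import annotations

from dataclasses import dataclass

COARSE_STAGES: tuple[str, ...] = ("I", "II", "III", "IV")
FINE_STAGES: tuple[str, ...] = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV", "I_IIA")

#: Coarse projection of each fine stage.  ``I_IIA`` spans coarse I and II and
#: has no unique projection; callers decide (see classifier.class_to_stage).
FINE_TO_COARSE: dict[str, str] = {
    "IA": "I",
    "IB": "I",
    "IIA": "II",
    "IIB": "II",
    "IIIA": "III",
    "IIIB": "III",
    "IV": "IV",
}


@dataclass(frozen=True)
class StageLabel:
    """A stage value tagged with its resolution.

    Parameters
    ----------
    resolution : {"coarse", "fine"}
    value : str
        One of ``COARSE_STAGES`` or ``FINE_STAGES`` according to resolution.
    """

    resolution: str
    value: str

    def __post_init__(self) -> None:
        if self.resolution == "coarse":
            allowed = COARSE_STAGES
        elif self.resolution == "fine":
            allowed = FINE_STAGES
        else:
            raise ValueError(f"unknown resolution {self.resolution!r}")
        if self.value not in allowed:
            raise ValueError(
                f"{self.value!r} is not a valid {self.resolution} stage"
            )

    @property
    def is_coarse(self) -> bool:
        return self.resolution == "coarse"

    def to_coarse(self) -> "StageLabel":
        """Project to the coarse scale (identity on coarse labels)."""
        if self.is_coarse:
            return self
        if self.value == "I_IIA":
            raise ValueError("I_IIA aggregate has no unique coarse projection")
        return coarse(FINE_TO_COARSE[self.value])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def coarse(value: str) -> StageLabel:
    return StageLabel("coarse", value)


def fine(value: str) -> StageLabel:
    return StageLabel("fine", value)


def parse_stage(text: str) -> StageLabel:
    """Parse a stage string from a patient table (coarse or fine spelling).

    "IV" is a valid spelling at both resolutions; the fine reading wins
    because it is the more informative one and projects losslessly to coarse.
    """
    text = text.strip().upper()
    if text in FINE_STAGES:
        return fine(text)
    if text in COARSE_STAGES:
        return coarse(text)
    raise ValueError(f"unrecognized stage label {text!r}")
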