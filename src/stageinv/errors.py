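"""Exception hierarchy for stageinv."""


class StageinvError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StageinvError):
    """An input table is missing a required column."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"missing required column {column!r}{where}")


class RowParseError(StageinvError):
    """A data row could not be parsed; carries the 1-based file line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class CodeMapConflictError(StageinvError):
    """The same (system, code) pair maps to two different concepts."""


class ContractError(StageinvError):
    """A function was called outside its contract (wrong resolution, empty group...)."""


class UndefinedMetricError(StageinvError):
    """A metric's denominator is zero so its value does not exist."""


class UndefinedCIError(StageinvError):
    """Bootstrap CI could not be formed: metric undefined in too many resamples."""

    def __init__(self, n_undefined: int, cap: int):
        self.n_undefined = n_undefined
        self.cap = cap
        super().__init__(
            f"metric undefined in {n_undefined} resamples (redraw cap {cap} reached)"
        )


class CalibrationError(StageinvError):
    """Survival calibration targets are infeasible (e.g. 5-year >= 2-year)."""
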