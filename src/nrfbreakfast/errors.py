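"""Exception hierarchy for the pipeline."""


class NRFBreakfastError(Exception):
    """Base class for all package errors."""


class SchemaError(NRFBreakfastError):
    """An input table is missing a required column."""


class RowParseError(NRFBreakfastError):
    """A data row could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class UnknownFoodError(NRFBreakfastError):
    """A recall line references a food code absent from the composition table."""

    def __init__(self, codes):
        self.codes = sorted(set(codes))
        super().__init__(
            "food codes not found in the composition table: "
            + ", ".join(map(str, self.codes))
        )


class ConfigError(NRFBreakfastError):
    """Invalid configuration (probabilities, SDs, reference values...)."""


class ScoringError(NRFBreakfastError):
    """An intake window cannot be scored (e.g. zero energy)."""


class QCError(NRFBreakfastError):
    """Outlier substitution failed (pathological percentile ordering)."""


class DependencyError(NRFBreakfastError):
    """A report stage is missing an upstream artifact; names the stage."""

    def __init__(self, stage: str, detail: str = ""):
        self.stage = stage
        msg = f"missing upstream artifact from stage '{stage}'"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
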