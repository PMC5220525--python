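"""Exception hierarchy for the msofa package."""

from __future__ import annotations


class MsofaError(Exception):
    """Base class for all msofa errors."""


class ValidationError(MsofaError, ValueError):
    """An input value is outside its physiological or formal range."""


class MissingDataError(MsofaError):
    """A variable required for the requested score is absent.

    Scoring never imputes: a missing required variable is an error, not a 0.
    """

    def __init__(self, variables, context: str = ""):
        if isinstance(variables, str):
            variables = [variables]
        self.variables = list(variables)
        msg = "missing required variable(s): " + ", ".join(self.variables)
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class DegenerateDataError(MsofaError):
    """The data cannot support the requested statistic (e.g. single-class
    outcomes for a ROC curve, zero variance for a correlation)."""


class CohortParseError(MsofaError):
    """A cohort CSV failed to parse; message carries row/column locations."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("cohort CSV parse failure:\n  " + "\n  ".join(self.problems))
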