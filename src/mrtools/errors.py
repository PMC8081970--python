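"""Exception and warning hierarchy."""


class MRToolsError(Exception):
    """Base class for all package errors."""


class SummaryTableError(MRToolsError):
    """A summary-statistic table could not be parsed; carries per-row messages."""

    def __init__(self, message, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class LDError(MRToolsError):
    """A variant is unknown to the LD matrix, or the matrix is malformed."""


class HarmonizationError(MRToolsError):
    """Exposure and outcome records cannot be aligned to a common allele."""


class EstimationError(MRToolsError):
    """An estimator precondition is violated (empty set, zero exposure effect, ...)."""


class ValueWarning(UserWarning):
    """A value is suspicious but usable (e.g. p inconsistent with beta/se)."""


class HarmonizationWarning(UserWarning):
    """Harmonization proceeded on partial evidence (e.g. missing other allele)."""
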