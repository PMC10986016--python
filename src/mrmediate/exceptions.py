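"""Exception hierarchy shared across the package.

``ParameterError`` covers user-supplied option/argument problems,
``ValidationError``/``FormatError`` cover malformed input data, and
``ConvergenceError`` covers numerical failures.  The CLI maps these onto
distinct exit codes.
"""

from __future__ import annotations


class MRError(Exception):
    """Base class for all package errors."""


class ParameterError(MRError, ValueError):
    """An option or argument is outside its admissible range."""


class FormatError(MRError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(MRError):
    """One or more data rows violate record invariants.

    ``rows`` holds 1-based file line numbers of the offending rows.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class InsufficientInstrumentsError(MRError):
    """Fewer SNPs than the method's minimum."""


class DegenerateInstrumentsError(MRError):
    """All instrument-exposure effects are zero; the Wald ratio is undefined."""


class MissingEAFError(MRError):
    """Effect-allele frequency absent where it is required (R^2 computation)."""


class CollinearityError(MRError):
    """Exposure columns in a multivariable design are (near) collinear."""

    def __init__(self, message: str, pair: tuple[str, str] | None = None):
        super().__init__(message)
        self.pair = pair


class ConvergenceError(MRError):
    """A root search or optimiser failed; carries the bracket tried."""

    def __init__(self, message: str, bracket: tuple[float, float] | None = None):
        super().__init__(message)
        self.bracket = bracket


class UndefinedProportionError(ParameterError):
    """Mediated proportion undefined because the total effect is zero."""


class PipelineStageError(MRError):
    """A pipeline stage failed; names the stage and the trait pair."""

    def __init__(self, stage: str, pair: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed for {pair}: {cause}")
        self.stage = stage
        self.pair = pair
        self.cause = cause
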