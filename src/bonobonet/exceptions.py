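"""Exception hierarchy for bonobonet.

Every error raised by the library derives from :class:`BonobonetError` so
callers (and the CLI) can distinguish library failures from programming
errors. Subclasses mark the validation stage that failed.
"""


class BonobonetError(Exception):
    """Base class for all bonobonet errors."""


class InputFormatError(BonobonetError):
    """A file could not be parsed (names the offending row/column)."""


class ValidationError(BonobonetError):
    """Input violates a structural requirement (duplicate ids, shape mismatch)."""


class DegenerateGeneError(ValidationError):
    """One or more genes carry no variance, breaking variance-based formulas."""

    def __init__(self, message: str, genes: list[str] | None = None):
        super().__init__(message)
        self.genes = genes or []


class InsufficientSamplesError(ValidationError):
    """Fewer samples than the leave-one-out machinery requires (N >= 3)."""


class ParameterError(BonobonetError):
    """A tuning parameter lies outside its admissible range."""


class DegreesOfFreedomError(ParameterError):
    """Prior degrees of freedom too small for the edge-variance formula."""


class StateError(BonobonetError):
    """An operation was requested before its prerequisites were computed."""
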