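"""Exception hierarchy shared across the toolkit."""


class NetoscError(Exception):
    """Base class for all toolkit errors."""


class InvalidModelError(NetoscError):
    """A generative model carries non-finite or out-of-range parameters."""


class ConfigurationError(NetoscError):
    """An unknown label or inconsistent configuration value was supplied."""


class InputError(NetoscError):
    """Input data violates a contract (duplicates, mismatched gene sets...)."""


class FormatError(InputError):
    """A file could not be parsed; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientDataError(NetoscError):
    """Too few time points for the requested statistic."""


class NormalizationError(NetoscError):
    """A row could not be normalized (zero mean without pseudocount)."""


class NoAnchorError(NetoscError):
    """A budding curve never reaches the 50% anchor."""


class InsufficientWindowError(NetoscError):
    """The series does not cover enough time past the first cycle."""


class EmptyReferenceError(NetoscError):
    """Overlap fraction requested against an empty reference set."""


class EmptyComparisonError(NetoscError):
    """No shared genes between the two estimate lists."""
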