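"""Exception hierarchy shared across the package."""


class HybriscopeError(Exception):
    """Base class for all package errors."""


class ParseError(HybriscopeError):
    """A file could not be parsed; the message names the offending cell/record."""


class ValidationError(HybriscopeError):
    """An in-memory object violates a documented invariant."""


class AnalysisError(HybriscopeError):
    """An analysis precondition is not met (e.g. all samples excluded)."""
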