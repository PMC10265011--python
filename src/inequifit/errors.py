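"""Exception hierarchy shared across the pipeline."""


class InequifitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(InequifitError, ValueError):
    """A value violates an operation's documented preconditions."""


class ConfigurationError(InequifitError, ValueError):
    """A configuration object is internally inconsistent."""


class DataError(InequifitError, ValueError):
    """A data table fails schema or referential-integrity validation.

    ``rows`` optionally carries the offending (0-based) row indices so CLI
    error messages can point at them.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else None
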