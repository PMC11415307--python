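"""Package-level exception types."""


class GJFluxError(Exception):
    """Base class for gjflux errors."""


class EstimationError(GJFluxError, RuntimeError):
    """A fit or estimator could not produce a usable result.

    Carries a ``diagnostics`` dict describing why (residuals, windows
    scanned, steps excluded, ...).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(GJFluxError, ValueError):
    """A delimited-text input file violated the documented format."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
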