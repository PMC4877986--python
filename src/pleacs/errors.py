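"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`PleacsError`,
so callers (and the CLI) can distinguish structured failures from bugs.
"""


class PleacsError(Exception):
    """Base class for all package errors."""


class CorpusParseError(PleacsError):
    """A corpus or labels file record could not be parsed.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class ValidationError(PleacsError):
    """A domain invariant was violated (duplicate ids, applicability rules...)."""


class DegenerateDesignError(PleacsError):
    """Trend analysis requested on a design with no usable variation."""
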