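"""Exception types shared across the package."""


class CvriskError(Exception):
    """Base class for all package errors."""


class DomainError(CvriskError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class FormatError(CvriskError, ValueError):
    """A file does not conform to the documented format (e.g. missing column)."""


class RowError(CvriskError, ValueError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class DegenerateInputError(CvriskError, ValueError):
    """Inputs make the requested statistic undefined (e.g. log-odds of 0 or 1)."""


class ConfigError(CvriskError, ValueError):
    """A configuration block is invalid or infeasible."""
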