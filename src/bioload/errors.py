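"""Exception hierarchy shared across the package."""


class BioloadError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BioloadError, ValueError):
    """An argument lies outside the mathematical domain of an index formula."""


class SchemaError(BioloadError, ValueError):
    """A table is structurally invalid (missing column, uneven element coverage...)."""


class RowError(SchemaError):
    """A single data row is invalid; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MissingGroupError(BioloadError, KeyError):
    """A (site, compartment, element) group was requested but is absent."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class ConfigError(BioloadError, ValueError):
    """A generator or pipeline configuration is invalid."""
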