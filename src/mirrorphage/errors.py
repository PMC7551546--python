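"""Exception hierarchy shared across the package."""


class MirrorphageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MirrorphageError):
    """Invalid or inconsistent configuration (exit code 2 in the CLI)."""


class DataError(MirrorphageError):
    """Malformed or unusable input data (exit code 3 in the CLI)."""


class ParseError(DataError):
    """A structured text file could not be parsed; carries a line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if path is not None and line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line
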