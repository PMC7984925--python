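"""Exception hierarchy for qmnet."""


class QmnetError(Exception):
    """Base class for all qmnet errors."""


class ParseError(QmnetError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ConfigError(QmnetError):
    """Invalid or incomplete pipeline configuration."""


class GenerationError(QmnetError):
    """Infeasible parameter combination for the synthetic-data generator."""
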