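"""Exception types shared across the pipeline."""


class StratEwasError(Exception):
    """Base class for all package errors."""


class ConfigError(StratEwasError):
    """Invalid configuration (bad frequencies, thresholds, dimensions...)."""


class DataIntegrityError(StratEwasError):
    """Inputs are mutually inconsistent (missing probes, duplicate ids...)."""


class ParseError(StratEwasError):
    """A file does not conform to its expected format."""

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
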