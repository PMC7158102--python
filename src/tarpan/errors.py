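"""Exception hierarchy for the tarpan engine."""


class TarpanError(Exception):
    """Base class for all errors raised by this package."""


class BedParseError(TarpanError):
    """A BED line failed to parse; carries file and 1-based line number."""

    def __init__(self, path, lineno: int, reason: str):
        self.path = str(path)
        self.lineno = lineno
        self.reason = reason
        super().__init__(f"{self.path}:{lineno}: {reason}")


class ConfigError(TarpanError):
    """The database registry (config.yml) could not be parsed."""


class ImportError_(TarpanError):
    """An ingest operation failed outright (as opposed to skipping rows)."""


class NormalizationError(TarpanError):
    """A normalization specification selects no usable intervals."""
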