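"""Exception types shared across the package."""


class SeasmortError(Exception):
    """Base class for package errors."""


class SchemaError(SeasmortError):
    """An input table is missing columns or contains out-of-range values."""


class UnmappedCodeError(SeasmortError):
    """One or more ICD codes matched no rule in the cause map (strict mode)."""

    def __init__(self, codes):
        self.codes = sorted(set(codes))
        super().__init__(f"unmappable ICD codes: {', '.join(self.codes)}")


class ConfigError(SeasmortError):
    """A simulation or pipeline configuration is invalid."""


class UndefinedCircularMeanError(SeasmortError):
    """The resultant vector has zero length; the mean direction is undefined."""


class BootstrapFailureError(SeasmortError):
    """The statistic was undefined in too many bootstrap replicates."""
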