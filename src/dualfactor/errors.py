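"""Exception hierarchy for the dualfactor package."""


class DualFactorError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DualFactorError):
    """An invalid generator or pipeline configuration.

    Carries the name of the offending field so callers (and the CLI) can
    point at the exact setting that failed validation.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class ValidationError(DualFactorError):
    """An argument outside its documented domain."""


class SchemaError(DualFactorError):
    """A respondent file that does not match the documented schema."""


class DegenerateInputError(DualFactorError):
    """Input that makes the requested statistic undefined (e.g. one-class ROC)."""


class DegenerateDesignError(DualFactorError):
    """A survey design with too little replication to estimate a variance."""
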