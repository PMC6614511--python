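"""Exception hierarchy for the cogmob pipeline."""


class CogmobError(Exception):
    """Base class for all cogmob errors."""


class ConfigurationError(CogmobError):
    """A generator or pipeline configuration field is invalid."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class SchemaError(CogmobError):
    """Input tables violate the expected schema (names the offending coordinate)."""


class MetadataError(CogmobError):
    """A variable references an unknown block or domain."""


class TransformDomainError(CogmobError):
    """A transformation is undefined on the given values."""


class RegressionRankError(CogmobError):
    """The covariate design matrix is rank deficient or has too few rows."""


class DegenerateCorrelationError(CogmobError):
    """A correlation is undefined because a residual vector has zero variance."""


class EmptyAnalysisError(CogmobError):
    """Every variable was excluded; there is nothing to analyse."""


class InputError(CogmobError):
    """A direct argument (not a file) is empty or out of range."""
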