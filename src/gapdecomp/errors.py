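"""Exception hierarchy shared across the package."""


class GapDecompError(Exception):
    """Base class for all package errors."""


class ConfigError(GapDecompError):
    """Invalid configuration (generator or run settings)."""


class SchemaError(GapDecompError):
    """Input table does not match the declared schema."""


class ValidationError(GapDecompError):
    """Input values violate type or range constraints."""


class CodingError(GapDecompError):
    """A covariate value falls outside its declared levels."""


class RankError(GapDecompError):
    """Design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class SeparationError(GapDecompError):
    """Perfect separation prevented the logit fit from converging."""

    def __init__(self, column):
        self.column = column
        super().__init__(f"perfect (or quasi-) separation detected; offending column: {column!r}")


class NotConvergedError(GapDecompError):
    """A fit flagged as non-converged was used downstream."""


class AssemblyError(GapDecompError):
    """Inconsistent pieces passed to the report assembler."""
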