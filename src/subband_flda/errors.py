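"""Exception hierarchy for the pipeline.

Stage code raises these; the CLI maps them to non-zero exit codes with the
failing stage named in the message.
"""


class SubbandFLDAError(Exception):
    """Base class for all package errors."""


class SignalParseError(SubbandFLDAError):
    """A data file could not be parsed into a finite numeric matrix."""


class ShapeError(SubbandFLDAError):
    """Array/label shapes are inconsistent."""


class ArgumentError(SubbandFLDAError):
    """An argument violates a precondition (negative threshold, bad level...)."""


class DataError(SubbandFLDAError):
    """Input data violates an invariant (non-finite values, empty record...)."""


class DegenerateFeatureError(SubbandFLDAError):
    """A feature column has zero variance and cannot be z-normalized."""


class DegenerateClassError(SubbandFLDAError):
    """A class has too few rows/subjects for the requested operation."""


class SingularityError(SubbandFLDAError):
    """A scatter matrix is singular along the requested direction."""


class ConfigError(SubbandFLDAError):
    """A pipeline configuration value is invalid."""
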