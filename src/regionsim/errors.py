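"""Exception hierarchy for regionsim."""


class RegionsimError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(RegionsimError, ValueError):
    """Invalid argument to a public operation."""


class ModelDefinitionError(RegionsimError):
    """Flow evaluator and stock declaration disagree."""


class NumericalError(RegionsimError):
    """A non-finite rate or stock value was produced."""


class ConfigurationError(RegionsimError):
    """Invalid parameter file, catalogue entry or run configuration."""


class AlignmentError(RegionsimError):
    """Observed and simulated series cannot be matched point-for-point."""
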