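"""Exception hierarchy shared across the pipeline stages."""


class PlantshiftError(Exception):
    """Base class for all package errors."""


class FormatError(PlantshiftError, ValueError):
    """An input file does not match the documented tabular dialect."""


class ValidationError(PlantshiftError, ValueError):
    """Data violates a domain invariant (negative mass, unknown group, ...)."""


class UnknownFoodError(PlantshiftError, KeyError):
    """A consumption event references a food_id absent from the database."""


class UnmappedGroupError(PlantshiftError, KeyError):
    """A disqualified food's group has no entry in the replacement table."""


class ConfigurationError(PlantshiftError, ValueError):
    """A reference pattern, scenario spec or run config is incomplete."""


class EstimationError(PlantshiftError, ValueError):
    """A habitual-intake stratum is too small or degenerate to estimate."""
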