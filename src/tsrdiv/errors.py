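"""Exception hierarchy used across the package."""


class TsrdivError(Exception):
    """Base class for all package errors."""


class ValidationError(TsrdivError):
    """Malformed or contract-violating input data."""


class ConfigError(TsrdivError):
    """Invalid configuration value."""


class FitError(TsrdivError):
    """Degenerate or failed model fit."""


class PlacementError(TsrdivError):
    """Synthetic features cannot be placed on the genome."""


class DesignError(TsrdivError):
    """Sample/group design does not meet an analysis precondition."""


class DegenerateVarianceError(TsrdivError):
    """A test statistic is undefined because the variance is zero."""
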