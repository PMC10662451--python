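"""Exception hierarchy for the flux-accounting pipeline."""


class FluxgapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FluxgapError):
    """Invalid user configuration (proportions, factor strata, missing masks)."""


class DataError(FluxgapError):
    """Inconsistent or contradictory input data (layer geometry, impossible states)."""


class EmptyStratumError(FluxgapError):
    """A summary statistic was requested over an empty cell selection."""


class UndefinedRatioError(FluxgapError):
    """A ratio or percentage difference has a zero denominator."""
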