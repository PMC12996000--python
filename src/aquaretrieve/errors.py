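"""Exception types shared across the toolbox."""


class AquaRetrieveError(Exception):
    """Base class for toolbox errors."""


class MissingBandError(AquaRetrieveError):
    """A declared band role could not be resolved or is absent from a scene."""


class GridConflictError(AquaRetrieveError):
    """Input rasters disagree on CRS or spatial extent."""


class ValidationError(AquaRetrieveError):
    """A configuration or argument failed validation."""


class InsufficientSamplesError(AquaRetrieveError):
    """Too few usable calibration rows for the requested fit."""
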