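"""Exception hierarchy for the heart-sound pipeline."""


class HeartSoundsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HeartSoundsError):
    """A configuration value is invalid (bad cutoff, order, probability...)."""


class DegenerateInputError(HeartSoundsError):
    """The input is too short, constant or otherwise carries no information."""


class SyncFailureError(HeartSoundsError):
    """The knock-artifact pattern could not be located in both channels."""


class EstimationFailureError(HeartSoundsError):
    """Cardiac timing could not be estimated (e.g. no ACF peak in the search window)."""
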