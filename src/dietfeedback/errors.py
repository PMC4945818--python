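"""Exception hierarchy for the dietary feedback engine."""


class DietFeedbackError(Exception):
    """Base class for all engine errors."""


class InputError(DietFeedbackError):
    """Invalid caller-supplied value (negative intake, bad band label, ...)."""


class ConfigurationError(DietFeedbackError):
    """Invalid reference configuration (non-increasing boundaries, registry mismatch)."""


class CatalogIntegrityError(DietFeedbackError):
    """Decision-tree / message-catalog inconsistency hit at resolution time."""
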