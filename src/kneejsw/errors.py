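"""Exception hierarchy for the measurement stack."""


class KneeJswError(Exception):
    """Base class for all package errors."""


class ValidationError(KneeJswError, ValueError):
    """An input violated a documented precondition."""


class SegmentationError(KneeJswError):
    """Bone segmentation could not produce two unambiguous bone masks."""


class MeasurementError(KneeJswError):
    """A measurement could not be completed (too few samples, missing edges...)."""
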