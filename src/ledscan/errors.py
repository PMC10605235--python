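"""Exception hierarchy.

Validation errors map to CLI exit code 2, processing errors to 3.
"""


class LedscanError(Exception):
    """Base class for all package errors."""


class ValidationError(LedscanError, ValueError):
    """Invalid parameters or inconsistent inputs, detected before processing."""


class FormatError(LedscanError, ValueError):
    """A serialized artifact does not match the expected schema."""


class SegmentationError(LedscanError, RuntimeError):
    """The image lacks the structure the segmentation model assumes."""


class GenerationError(LedscanError, RuntimeError):
    """Synthetic scene could not be realized under the placement constraints."""


class ProcessingError(LedscanError, RuntimeError):
    """A pipeline stage failed on an otherwise valid input."""
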