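"""Exception hierarchy for the planimetry pipeline.

The CLI maps these onto exit codes: configuration / input problems -> 3,
detection or segmentation failures on an otherwise valid image -> 2.
"""


class AvaplanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AvaplanError):
    """Invalid parameter, geometry specification, or config file."""


class InputError(AvaplanError):
    """Unreadable or unsupported input (missing spacing, multi-frame, ...)."""


class DetectionError(AvaplanError):
    """Sinus-of-Valsalva detection failed; the user should crop manually."""


class SegmentationError(AvaplanError):
    """Segmentation produced no usable orifice object."""


class NumericalError(AvaplanError):
    """A numerical solver diverged or produced non-finite values."""
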