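"""Exception types raised by the pipeline stages."""


class OdsegError(Exception):
    """Base class for all package errors."""

    code = "odseg_error"


class ParameterError(OdsegError, ValueError):
    """A parameter or scene specification violates its documented bounds."""

    code = "parameter_error"


class InputError(OdsegError, ValueError):
    """An input raster/mask is unusable (wrong shape, empty, degenerate)."""

    code = "input_error"


class LocalizationError(OdsegError, RuntimeError):
    """Optic-disc localization produced no candidate region."""

    code = "localization_failure"


class SegmentationError(OdsegError, RuntimeError):
    """No admissible optic-disc candidate survived selection."""

    code = "segmentation_failure"


class EllipseFitError(OdsegError, RuntimeError):
    """Ellipse fitting failed (too few or degenerate boundary points)."""

    code = "ellipse_fit_failure"
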